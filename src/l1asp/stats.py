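"""Cohort statistics and the summary report.

Holds the chi-squared goodness-of-fit test used for the sense/antisense
strand-bias question (observed category counts against null proportions,
default an equal split), Benjamini-Hochberg FDR adjustment, and the
headline-fraction report where every percentage is printed alongside its
numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests


def _log_chi2_sf(chi2: float, df: int) -> float:
    """Natural-log survival function, robust to underflow at huge statistics."""
    p = float(sps.chi2.sf(chi2, df))
    if p > 0:
        return float(np.log(p))
    if df == 1:
        # P(X > x) = erfc(sqrt(x/2)) = 2 * Phi(-sqrt(x))
        return float(np.log(2.0) + special.log_ndtr(-np.sqrt(chi2)))
    # upper incomplete gamma asymptotics: Q(a, x) ~ x^(a-1) e^-x / Gamma(a)
    a, x = df / 2.0, chi2 / 2.0
    return float((a - 1.0) * np.log(x) - x - special.gammaln(a))


@dataclass
class GofResult:
    observed: tuple[int, ...]
    expected_proportions: tuple[float, ...]
    chi2: float
    df: int
    p_value: float
    log10_p: float


def chi2_gof(
    observed: Sequence[int], expected_proportions: Optional[Sequence[float]] = None
) -> GofResult:
    """Chi-squared goodness of fit of counts against null proportions.

    Default null: equal proportions across categories.  ``log10_p`` is
    computed from the survival function in log space so extreme statistics
    (far below the float underflow of ``p_value``) remain meaningful.
    """
    obs = np.asarray(observed, dtype=np.float64)
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("observed counts must be non-negative with a positive total")
    k = len(obs)
    if expected_proportions is None:
        props = np.full(k, 1.0 / k)
    else:
        props = np.asarray(expected_proportions, dtype=np.float64)
        if len(props) != k or not np.isclose(props.sum(), 1.0):
            raise ValueError("expected proportions must match categories and sum to 1")
    expected = obs.sum() * props
    if np.any(expected == 0):
        raise ValueError("zero expected count in a category")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    log10_p = _log_chi2_sf(chi2, df) / float(np.log(10.0))
    return GofResult(
        observed=tuple(int(o) for o in obs),
        expected_proportions=tuple(float(x) for x in props),
        chi2=chi2,
        df=df,
        p_value=p,
        log10_p=log10_p,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """A printed percentage: 100 * n / d rounded to ``decimals`` (default 1)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


@dataclass
class Fraction:
    label: str
    numerator: int
    denominator: int

    @property
    def pct(self) -> float:
        return percent(self.numerator, self.denominator)


def cohort_report(
    screen_summary=None,
    coding_summary=None,
    profiles: Optional[Mapping[str, object]] = None,
    extra_fractions: Optional[Mapping[str, tuple[int, int]]] = None,
) -> dict:
    """Aggregate the headline fractions of a full pipeline run.

    Every percentage in the output is count/denominator arithmetic on the
    upstream modules' tallies; denominators are always reported alongside.
    Returns a plain dict (JSON-serializable); see :func:`report_markdown`.
    """
    fractions: list[Fraction] = []
    out: dict = {"fractions": []}
    if screen_summary is not None:
        n_ov = screen_summary.n_pairwise_overlaps
        n_acc = screen_summary.n_accepted
        out["n_accepted_transcripts"] = n_acc
        out["n_genes"] = len(screen_summary.per_gene_est_counts)
        out["n_pairwise_overlaps"] = n_ov
        if n_ov:
            fractions.append(Fraction("sense_overlaps", screen_summary.sense_overlaps, n_ov))
            fractions.append(
                Fraction("antisense_overlaps", screen_summary.antisense_overlaps, n_ov)
            )
        if n_acc:
            for cls, cnt in sorted(screen_summary.subfamily_class_counts.items()):
                fractions.append(Fraction(f"class_{cls}", cnt, n_acc))
            fractions.append(
                Fraction("multi_alignment", screen_summary.n_multi_alignment, n_acc)
            )
        if screen_summary.sense_overlaps + screen_summary.antisense_overlaps > 0:
            gof = chi2_gof(
                [screen_summary.sense_overlaps, screen_summary.antisense_overlaps]
            )
            out["strand_bias"] = {
                "chi2": gof.chi2,
                "df": gof.df,
                "p_value": gof.p_value,
                "log10_p": gof.log10_p,
            }
    if coding_summary is not None:
        fractions.append(
            Fraction("coding", coding_summary.n_coding, coding_summary.n_transcripts)
        )
        out["peptide_length_aa"] = {
            "mean": coding_summary.peptide_mean_aa,
            "min": coding_summary.peptide_min_aa,
            "max": coding_summary.peptide_max_aa,
        }
    if profiles:
        out["tss_profiles"] = {
            cls: {"n": prof.n, "n_unmappable": len(prof.unmappable),
                  "mode_percent": prof.mode_percent() if prof.n else None}
            for cls, prof in profiles.items()
        }
    if extra_fractions:
        for label, (num, den) in extra_fractions.items():
            fractions.append(Fraction(label, num, den))
    out["fractions"] = [
        {"label": f.label, "n": f.numerator, "of": f.denominator, "pct": f.pct}
        for f in fractions
    ]
    return out


def report_markdown(report: dict) -> str:
    """Render a cohort report dict as a small Markdown document."""
    lines = ["# L1 ASP screen summary", ""]
    for key in ("n_accepted_transcripts", "n_genes", "n_pairwise_overlaps"):
        if key in report:
            lines.append(f"- {key.replace('_', ' ')}: {report[key]}")
    if "strand_bias" in report:
        sb = report["strand_bias"]
        lines.append(
            f"- strand bias: chi2 = {sb['chi2']:.1f} (df {sb['df']}), "
            f"log10 p = {sb['log10_p']:.1f}"
        )
    if report["fractions"]:
        lines += ["", "| quantity | n | of | % |", "|---|---|---|---|"]
        for f in report["fractions"]:
            lines.append(f"| {f['label']} | {f['n']} | {f['of']} | {f['pct']} |")
    if "peptide_length_aa" in report:
        pl = report["peptide_length_aa"]
        lines.append("")
        lines.append(
            f"- coding peptides: {pl['min']}-{pl['max']} aa, mean {pl['mean']:.0f} aa"
        )
    return "\n".join(lines) + "\n"
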