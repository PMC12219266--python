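"""Group statistics supporting the kinetics pipeline.

Welch's unequal-variances t test compares kinetic constants between enzyme
variants (e.g. wild type vs the F63S population variant); two-tailed t
tests with Benjamini-Hochberg control at FDR 0.05 screen metabolite
abundance tables; and a simple competitive-rate argument predicts how much
slower a variant with an elevated histidine Km runs at physiological
histidine concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .optics import OpticalCalibration, absorbance_to_concentration, \
    pathlength_from_water_band

__all__ = [
    "VariantComparison",
    "EndpointSummary",
    "welch_t",
    "bh_adjust",
    "diff_abundance",
    "predict_rate_ratio",
    "summarize_endpoint_screen",
]


@dataclass
class VariantComparison:
    """Welch's t comparison of one constant between two groups."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    diff: float            # mean_a - mean_b
    ci_low: float
    ci_high: float
    fold_change: float     # mean_b / mean_a
    n_a: int
    n_b: int


def welch_t(group_a, group_b, ci: float = 0.95) -> VariantComparison:
    """Welch's unequal-variances t test with a CI on the mean difference.

    Two-tailed p from the Welch-Satterthwaite degrees of freedom; the CI of
    mean(a) - mean(b) uses the t quantile at that df.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups (degenerate input)")
    res = sps.ttest_ind(a, b, equal_var=False)
    sa2, sb2 = va / len(a), vb / len(b)
    df = (sa2 + sb2) ** 2 / (sa2 ** 2 / (len(a) - 1) + sb2 ** 2 / (len(b) - 1))
    diff = float(a.mean() - b.mean())
    half = sps.t.ppf(0.5 + ci / 2, df) * np.sqrt(sa2 + sb2)
    return VariantComparison(
        t=float(res.statistic), df=float(df), p=float(res.pvalue),
        mean_a=float(a.mean()), mean_b=float(b.mean()), diff=diff,
        ci_low=diff - float(half), ci_high=diff + float(half),
        fold_change=float(b.mean() / a.mean()) if a.mean() != 0 else np.inf,
        n_a=len(a), n_b=len(b),
    )


def bh_adjust(pvalues, fdr: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(qvalues, reject)``: monotone adjusted p-values and the
    significance flags at the given FDR.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, reject


def diff_abundance(
    table: pd.DataFrame, group_a_cols, group_b_cols, fdr: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-metabolite two-tailed t tests with BH control at ``fdr``.

    ``table`` has metabolites as rows and replicate samples as columns.
    Welch's test by default (``equal_var=True`` switches to Student's).
    Returns a tidy frame with group means, raw p, BH q and the flag.
    """
    a = table[list(group_a_cols)].to_numpy(dtype=float)
    b = table[list(group_b_cols)].to_numpy(dtype=float)
    res = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    q, flag = bh_adjust(res.pvalue, fdr=fdr)
    return pd.DataFrame({
        "metabolite": table.index,
        "mean_a": a.mean(axis=1),
        "mean_b": b.mean(axis=1),
        "p": res.pvalue,
        "q": q,
        "significant": flag,
    }).set_index("metabolite")


def predict_rate_ratio(km_ref: float, km_var: float, substrate_uM: float):
    """Fold-reduction of the variant rate at one substrate concentration.

    Assuming equal Vmax, v_ref / v_var = (Km_var + S) / (Km_ref + S): an
    elevated Km slows the enzyme most where S is far below Km.  Returns
    ``(fold, rounded_fold)`` — the real ratio and its nearest integer (the
    convention used when quoting "n-fold slower").
    """
    if km_ref <= 0 or km_var <= 0 or substrate_uM <= 0:
        raise ValueError("Km values and substrate concentration must be positive")
    fold = (km_var + substrate_uM) / (km_ref + substrate_uM)
    return float(fold), int(round(fold))


@dataclass
class EndpointSummary:
    """Replicate-level summary for one substrate in the endpoint screen."""

    substrate: str
    replicate_uM: list
    mean_uM: float
    control_mean_uM: float
    net_mean_uM: float
    n_reaction: int
    n_control: int


def summarize_endpoint_screen(
    plate: pd.DataFrame, calibration: OpticalCalibration | None = None,
) -> list[EndpointSummary]:
    """Summarize a 30-min endpoint screen plate.

    Converts endpoint A412 to CoA formed (µM) per well using the per-well
    water-band pathlength, averages the reaction replicates per substrate
    and subtracts that substrate's no-enzyme control mean.  Individual
    replicate values are preserved.
    """
    cal = calibration or OpticalCalibration.for_assay("endpoint", blank_a412=0.04)
    out = []
    for substrate, g in plate.groupby("substrate", sort=False):
        conc = {}
        for role, gg in g.groupby("role"):
            vals = [
                float(absorbance_to_concentration(
                    row.a412,
                    pathlength_from_water_band(row.a975, row.a900,
                                               cal.pathlength_divisor),
                    cal,
                ))
                for row in gg.itertuples()
            ]
            conc[role] = vals
        if "control" not in conc or not conc["control"]:
            raise ValueError(f"no control wells for substrate {substrate!r}")
        reaction = conc.get("reaction", [])
        mean = float(np.mean(reaction)) if reaction else np.nan
        ctrl = float(np.mean(conc["control"]))
        out.append(EndpointSummary(
            substrate=substrate,
            replicate_uM=reaction,
            mean_uM=mean,
            control_mean_uM=ctrl,
            net_mean_uM=mean - ctrl,
            n_reaction=len(reaction),
            n_control=len(conc["control"]),
        ))
    return out
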