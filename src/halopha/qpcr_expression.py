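"""RT-qPCR quantification: standard curves, Pfaffl ratios, transcript proxies.

Ct tables are long-format :class:`pandas.DataFrame` objects with columns
``gene, condition, bio_rep, tech_rep, ct`` (an optional ``phase`` column is
carried through untouched; "condition" is whatever label defines a
comparison group, e.g. a growth phase or a medium).

The quantification chain follows the standard efficiency-corrected
workflow:

1. *Standard curves.* Ct is regressed on log10 template quantity over a
   10-fold dilution series; the amplification efficiency is
   ``E = 10**(-1/slope)`` (ideal E = 2, one doubling per cycle).
2. *Technical replicates* are averaged per biological replicate.
3. *Pfaffl ratio.* ``R = E_t**dCt_t / NF`` with
   ``dCt = mean Ct(control) - mean Ct(sample)`` and ``NF`` the geometric
   mean over reference genes of ``E_r**dCt_r`` (geNorm-style multi-reference
   normalisation; a single reference is its own geometric mean).
4. *Group comparison.* Two-sided unpaired t-test on per-biological-replicate
   reference-normalised Ct values (Ct_target − mean Ct_references), with a
   Shapiro–Wilk normality check per group that warns but never blocks.
5. *Absolute proxies.* ``Q = 10**((ct - intercept)/slope)`` converts a Ct to
   a relative template quantity on the standard curve's scale, enabling
   cross-gene comparisons of transcript levels.

Per-replicate ratio spread pairs each sample biological replicate against
the control-condition mean; an all-pairs alternative is available via
``pairing="all_pairs"``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CT_COLUMNS = ("gene", "condition", "bio_rep", "tech_rep", "ct")

#: Plausibility band for amplification efficiencies; outside -> QC warning.
EFFICIENCY_QC_RANGE = (1.8, 2.1)
R_SQUARED_QC_MIN = 0.98
TECH_DIVERGENCE_CYCLES = 0.5


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration Ct = slope * log10(quantity) + intercept."""

    gene: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification factor, E = 10**(-1/slope)."""
        return 10.0 ** (-1.0 / self.slope)


@dataclass
class ExpressionComparison:
    gene: str
    sample: str
    control: str
    ratio: float
    ratio_sd: float
    p_value: float
    normality_ok: tuple[bool | None, bool | None]
    references_used: tuple[str, ...] = field(default_factory=tuple)


def fit_standard_curve(
    series: Sequence[tuple[float, float]] | pd.DataFrame,
    gene: str = "",
) -> StandardCurve:
    """OLS fit of Ct against log10 relative quantity for a dilution series.

    ``series`` is an iterable of ``(log10_quantity, ct)`` pairs or a frame
    with columns ``log10_quantity`` and ``ct``.  Requires >= 3 distinct
    dilution points.  Warns (never fails) when the efficiency leaves the QC
    band or r² < 0.98.
    """
    if isinstance(series, pd.DataFrame):
        x = series["log10_quantity"].to_numpy(float)
        y = series["ct"].to_numpy(float)
    else:
        arr = np.asarray(list(series), dtype=float)
        if arr.size == 0:
            raise ValueError("empty dilution series")
        x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("standard curve needs >= 3 distinct dilution points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in dilution quantities")
    fit = stats.linregress(x, y)
    curve = StandardCurve(gene, float(fit.slope), float(fit.intercept),
                          float(fit.rvalue) ** 2)
    if curve.slope >= 0:
        warnings.warn(f"{gene or 'curve'}: non-negative slope, curve invalid")
    else:
        lo, hi = EFFICIENCY_QC_RANGE
        if not lo < curve.efficiency < hi:
            warnings.warn(
                f"{gene or 'curve'}: efficiency {curve.efficiency:.3f} outside ({lo}, {hi})"
            )
    if curve.r_squared < R_SQUARED_QC_MIN:
        warnings.warn(f"{gene or 'curve'}: r^2 {curve.r_squared:.4f} < {R_SQUARED_QC_MIN}")
    return curve


def fit_all_curves(dilutions: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per gene from a long dilution table
    (columns gene, log10_quantity, ct)."""
    return {
        str(gene): fit_standard_curve(sub, gene=str(gene))
        for gene, sub in dilutions.groupby("gene", sort=True)
    }


def collapse_technical(measurements: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates per (gene, condition[, phase], bio_rep).

    Warns when the within-replicate technical range exceeds 0.5 cycles.
    """
    keys = [c for c in ("gene", "condition", "phase", "bio_rep")
            if c in measurements.columns]
    grouped = measurements.groupby(keys, sort=True)["ct"]
    spread = grouped.agg(lambda s: s.max() - s.min())
    divergent = spread[spread > TECH_DIVERGENCE_CYCLES]
    for key, rng in divergent.items():
        warnings.warn(f"technical replicates diverge by {rng:.2f} cycles at {key}")
    return grouped.mean().reset_index()


def reference_normalization_factor(ref_quantities: Mapping[str, float]) -> float:
    """Geometric mean of per-reference relative quantities (a single
    reference is returned unchanged)."""
    if not ref_quantities:
        raise ValueError("no reference quantities given")
    values = np.array(list(ref_quantities.values()), dtype=float)
    if np.any(values <= 0):
        raise ValueError("reference quantities must be positive")
    if len(values) == 1:
        return float(values[0])
    return float(np.exp(np.mean(np.log(values))))


def _condition_cts(collapsed: pd.DataFrame, gene: str, condition: str) -> pd.Series:
    sub = collapsed[(collapsed["gene"] == gene) & (collapsed["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"no Ct data for gene {gene!r} in condition {condition!r}")
    return sub.set_index("bio_rep")["ct"].sort_index()


def pfaffl_ratio(
    measurements: pd.DataFrame,
    gene: str,
    reference_genes: Sequence[str],
    curves: Mapping[str, StandardCurve] | Mapping[str, float],
    control: str,
    sample: str,
    pairing: str = "control_mean",
) -> ExpressionComparison:
    """Efficiency-corrected relative expression of ``sample`` vs ``control``.

    ``curves`` maps gene name to either a :class:`StandardCurve` or a bare
    efficiency.  Technical replicates are collapsed internally.  The
    headline ratio uses condition means; the spread (``ratio_sd``) comes
    from per-biological-replicate ratios, each sample replicate paired
    against the control mean (or against every control replicate with
    ``pairing="all_pairs"``).  The p-value tests reference-normalised Ct
    values between conditions.
    """
    if not reference_genes:
        raise ValueError("at least one reference gene required")

    def eff(g: str) -> float:
        c = curves[g]
        return c.efficiency if isinstance(c, StandardCurve) else float(c)

    collapsed = collapse_technical(measurements)
    t_ctrl = _condition_cts(collapsed, gene, control)
    t_samp = _condition_cts(collapsed, gene, sample)
    refs_ctrl = {r: _condition_cts(collapsed, r, control) for r in reference_genes}
    refs_samp = {r: _condition_cts(collapsed, r, sample) for r in reference_genes}

    e_t = eff(gene)
    dct_t = t_ctrl.mean() - t_samp.mean()
    num = e_t ** dct_t
    nf = reference_normalization_factor(
        {r: eff(r) ** (refs_ctrl[r].mean() - refs_samp[r].mean())
         for r in reference_genes}
    )
    ratio = num / nf

    per_rep: list[float] = []
    ctrl_anchor = [t_ctrl.mean()] if pairing == "control_mean" else list(t_ctrl)
    ref_anchor = {
        r: ([refs_ctrl[r].mean()] if pairing == "control_mean" else list(refs_ctrl[r]))
        for r in reference_genes
    }
    for b in t_samp.index:
        for i, anchor in enumerate(ctrl_anchor):
            r_num = e_t ** (anchor - t_samp[b])
            r_nf = reference_normalization_factor(
                {r: eff(r) ** (ref_anchor[r][i] - refs_samp[r][b])
                 for r in reference_genes}
            )
            per_rep.append(r_num / r_nf)
    ratio_sd = float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0

    # group test on reference-normalised Ct values
    norm_ctrl = _normalized_cts(t_ctrl, refs_ctrl)
    norm_samp = _normalized_cts(t_samp, refs_samp)
    p_value, normality = compare_conditions(norm_ctrl, norm_samp)

    return ExpressionComparison(
        gene=gene,
        sample=sample,
        control=control,
        ratio=float(ratio),
        ratio_sd=ratio_sd,
        p_value=p_value,
        normality_ok=normality,
        references_used=tuple(reference_genes),
    )


def _normalized_cts(target: pd.Series, refs: Mapping[str, pd.Series]) -> np.ndarray:
    ref_mean = pd.concat(refs.values(), axis=1).mean(axis=1)
    aligned = target - ref_mean.reindex(target.index)
    if aligned.isna().any():
        raise ValueError("reference gene missing biological replicates present in target")
    return aligned.to_numpy(float)


def absolute_quantity(ct: float, curve: StandardCurve) -> float:
    """Relative template quantity from a Ct via the standard curve:
    ``Q = 10**((ct - intercept)/slope)``; strictly decreasing in Ct."""
    if curve.slope >= 0:
        raise ValueError("standard curve slope must be negative")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def compare_conditions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, tuple[bool | None, bool | None]]:
    """Two-sided unpaired t-test between two groups of per-replicate values.

    Equal variances are assumed by default (classic Student test); set
    ``welch=True`` for the unequal-variance variant.  Shapiro–Wilk is run
    per group when n >= 3; a failure (p < 0.05) flags the group as
    non-normal and logs a warning but does not block the t-test.  Groups of
    size < 3 get a ``None`` flag (normality not assessable).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 biological replicates")

    flags: list[bool | None] = []
    for name, grp in (("a", a), ("b", b)):
        if len(grp) >= 3 and np.ptp(grp) > 0:
            with warnings.catch_warnings():
                # near-identical replicates trip scipy's precision warning
                warnings.simplefilter("ignore", RuntimeWarning)
                ok = bool(stats.shapiro(grp).pvalue >= 0.05)
            if not ok:
                warnings.warn(f"group {name} fails Shapiro-Wilk normality check")
            flags.append(ok)
        else:
            flags.append(None)

    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 1.0, (flags[0], flags[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue), (flags[0], flags[1])


def quantify_all(
    measurements: pd.DataFrame,
    curves: Mapping[str, StandardCurve],
) -> pd.DataFrame:
    """Absolute transcript proxies for every collapsed Ct measurement
    (columns of the input plus ``quantity``)."""
    collapsed = collapse_technical(measurements)
    collapsed["quantity"] = [
        absolute_quantity(row.ct, curves[row.gene])
        for row in collapsed.itertuples()
    ]
    return collapsed
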