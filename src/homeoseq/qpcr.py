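"""qPCR standard curves and efficiency-corrected relative quantification.

A serial-dilution standard curve regresses Ct on log10 relative input; the
amplification efficiency is E = 10^(-1/slope) (E = 2 means perfect
doubling, reported as 100 %).  Relative quantification follows the
efficiency-corrected ΔΔCt scheme

    RQ = E_target^(-ΔCt_target) / E_endo^(-ΔCt_endo),

with ΔCt = mean Ct(treatment) - mean Ct(control); with E = 2 for both
genes this reduces exactly to 2^(-ΔΔCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ENDOGENOUS = "Ubiquitin"


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    group: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # fold amplification per cycle; 2.0 == 100 %
    valid: bool = True

    @property
    def efficiency_percent(self) -> float:
        return (self.efficiency - 1.0) * 100.0


def fit_standard_curve(
    dilution_log10: Sequence[float],
    ct: Sequence[float],
    gene: str = "",
    group: str = "",
) -> StandardCurve:
    """Least-squares standard curve Ct ~ log10(relative input).

    Requires >= 3 points at distinct dilutions.  A non-negative slope
    cannot arise from real amplification and flags the curve invalid
    (efficiency reported as NaN).
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 (dilution, Ct) points")
    if len(np.unique(x)) < 2:
        raise ValueError("dilutions must not all coincide")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope >= 0:
        return StandardCurve(
            gene, group, slope, float(fit.intercept),
            float(fit.rvalue**2), float("nan"), valid=False,
        )
    eff = float(10.0 ** (-1.0 / slope))
    return StandardCurve(
        gene, group, slope, float(fit.intercept), float(fit.rvalue**2), eff
    )


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Ct table TSV with columns gene, group, replicate, ct."""
    tab = pd.read_csv(path, sep="\t")
    required = {"gene", "group", "replicate", "ct"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (tab["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return tab


def _mean_ct(ct: pd.DataFrame, gene: str, group: str) -> float:
    sel = ct[(ct["gene"] == gene) & (ct["group"] == group)]["ct"]
    if sel.empty:
        raise ValueError(f"no Ct measurements for gene {gene!r} in group {group!r}")
    return float(sel.mean())


def _gene_efficiency(
    curves: Sequence[StandardCurve], gene: str, treatment: str, control: str
) -> float:
    """Effective per-gene efficiency from group-specific standard curves.

    Uses the geometric mean of the treatment- and control-group curves
    when both exist, a single group's curve when only one does, and the
    perfect-doubling default E = 2 when none is available.
    """
    by_group = {
        c.group: c.efficiency
        for c in curves
        if c.gene == gene and c.valid and np.isfinite(c.efficiency)
    }
    effs = [by_group[g] for g in (treatment, control) if g in by_group]
    if not effs:
        return 2.0
    return float(np.exp(np.mean(np.log(effs))))


def relative_quantification(
    ct: pd.DataFrame,
    curves: Sequence[StandardCurve],
    target_gene: str,
    treatment_group: str,
    control_group: str,
    endogenous_gene: str = DEFAULT_ENDOGENOUS,
) -> float:
    """Efficiency-corrected relative expression of target vs endogenous gene.

    Replicate Cts are averaged arithmetically before ΔCt.  Raises when the
    endogenous gene is missing in either group.
    """
    dct_target = (
        _mean_ct(ct, target_gene, treatment_group)
        - _mean_ct(ct, target_gene, control_group)
    )
    try:
        dct_endo = (
            _mean_ct(ct, endogenous_gene, treatment_group)
            - _mean_ct(ct, endogenous_gene, control_group)
        )
    except ValueError as err:
        raise ValueError(
            f"endogenous gene {endogenous_gene!r} missing: {err}"
        ) from err
    e_target = _gene_efficiency(curves, target_gene, treatment_group, control_group)
    e_endo = _gene_efficiency(curves, endogenous_gene, treatment_group, control_group)
    return float(e_target ** (-dct_target) / e_endo ** (-dct_endo))


def curves_to_frame(curves: Sequence[StandardCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "group": c.group,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "efficiency": c.efficiency,
                "efficiency_percent": c.efficiency_percent,
                "valid": c.valid,
            }
            for c in curves
        ]
    )


def curves_from_frame(tab: pd.DataFrame) -> list[StandardCurve]:
    return [
        StandardCurve(
            str(r.gene), str(r.group), float(r.slope), float(r.intercept),
            float(r.r_squared), float(r.efficiency), bool(r.valid),
        )
        for r in tab.itertuples()
    ]
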