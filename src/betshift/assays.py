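"""Wet-lab assay models: efficiency-corrected RT-qPCR quantification and
the proliferation response-area statistic.

Relative transcript abundance uses the efficiency-corrected delta-Ct
form X = (1+EffR)^CtR / (1+EffX)^CtX, with per-primer amplification
efficiencies Eff in (0, 1] (1 = perfect doubling per cycle). Treated
values are conventionally rescaled so the vehicle (DMSO) group mean is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class QPCRMeasurement:
    sample: str
    condition: str     # "DMSO" or "treated"
    replicate: int
    ct_target: float   # CtX: threshold cycle of the target transcript
    ct_ref: float      # CtR: threshold cycle of the reference transcript
    eff_target: float  # EffX in (0, 1]
    eff_ref: float     # EffR in (0, 1]

    def __post_init__(self):
        if self.ct_target <= 0 or self.ct_ref <= 0:
            raise ValueError("Ct values must be positive")
        if not (0 < self.eff_target <= 1 and 0 < self.eff_ref <= 1):
            raise ValueError("efficiencies must lie in (0, 1]")


def qpcr_expression(m: QPCRMeasurement) -> float:
    """Relative abundance X = (1+EffR)^CtR / (1+EffX)^CtX."""
    return (1.0 + m.eff_ref) ** m.ct_ref / (1.0 + m.eff_target) ** m.ct_target


def qpcr_table_expression(df: pd.DataFrame) -> pd.Series:
    """Vectorized qpcr_expression over a Ct table with columns ct_target,
    ct_ref, eff_target, eff_ref."""
    for col in ("eff_target", "eff_ref"):
        if ((df[col] <= 0) | (df[col] > 1)).any():
            raise ValueError("efficiencies must lie in (0, 1]")
    return (1.0 + df["eff_ref"]) ** df["ct_ref"] / (1.0 + df["eff_target"]) ** df["ct_target"]


def normalize_to_dmso(values: pd.Series, conditions: pd.Series,
                      vehicle: str = "DMSO") -> pd.Series:
    """Divide every value by the vehicle-group mean, so the vehicle mean of
    the output is exactly 1."""
    mask = conditions == vehicle
    if not mask.any():
        raise ValueError(f"no {vehicle!r} measurements to normalize against")
    return values / values[mask].mean()


def paired_expression_test(dmso, treated) -> tuple:
    """Two-sided paired t-test with the conventional star annotation:
    '**' for p < 0.005, '*' for p < 0.05, '' otherwise.

    Identical vectors (zero-variance differences) are flagged with p = 1
    rather than an undefined statistic.
    """
    dmso = np.asarray(dmso, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if len(dmso) != len(treated) or len(dmso) < 2:
        raise ValueError("paired test needs equal-length vectors of >= 2 replicates")
    diffs = treated - dmso
    if np.allclose(diffs.std(ddof=1), 0.0):
        p = 1.0 if np.allclose(diffs, 0.0) else 0.0
    else:
        p = float(stats.ttest_rel(treated, dmso).pvalue)
    star = "**" if p < 0.005 else ("*" if p < 0.05 else "")
    return p, star


@dataclass
class DoseResponse:
    """Viability fractions on a strictly increasing concentration grid."""

    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        if len(c) != len(v) or len(c) < 2:
            raise ValueError("need matching concentration/viability grids of length >= 2")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentration grid must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive (log scale)")
        if np.any(v < 0) or np.any(v > 1.0 + 1e-6):
            raise ValueError("viability must lie in [0, 1]")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "viability", v)

    @property
    def response(self) -> np.ndarray:
        return 1.0 - self.viability


def response_area(d: DoseResponse) -> float:
    """Normalized response area: the trapezoidal integral of (1 - viability)
    over log10 concentration, divided by the log-range. 0 means no
    response anywhere on the tested range, 1 complete loss of viability."""
    x = np.log10(d.concentrations)
    area = np.trapezoid(d.response, x)
    return float(area / (x[-1] - x[0]))


def select_reference_genes(de_tables: dict, expression_means: pd.DataFrame,
                           max_dose: float = 500.0, fdr: float = 0.05,
                           quantile: float = 0.8) -> pd.DataFrame:
    """Rank reference-gene candidates for qPCR normalization.

    A candidate must be (1) unaffected by treatment — no significant
    expression change in any model at doses up to ``max_dose`` — and
    (2) expressed above the ``quantile`` expression quantile in every
    model. ``de_tables`` maps (model, dose) -> DE table; ``expression_means``
    holds per-model mean expression columns. Candidates are returned ranked
    by their largest absolute LFC across the considered contrasts
    (smallest first).
    """
    genes = expression_means.index
    ok = pd.Series(True, index=genes)
    max_abs_lfc = pd.Series(0.0, index=genes)
    for (model, dose), de in de_tables.items():
        if dose > max_dose:
            continue
        de = de.reindex(genes)
        ok &= ~((de["padj"] < fdr) & de["padj"].notna())
        max_abs_lfc = np.maximum(max_abs_lfc, de["lfc"].abs().fillna(np.inf))
    for col in expression_means.columns:
        ok &= expression_means[col] >= expression_means[col].quantile(quantile)
    out = pd.DataFrame({"max_abs_lfc": max_abs_lfc[ok]}).sort_values("max_abs_lfc")
    return out
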