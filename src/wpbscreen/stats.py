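"""Per-well statistics and plate-level screen analysis.

Four well summaries describe the WPB phenotype of a well, each the mean of
the per-field-of-view values:

* ``PercentWPBarea`` — area fraction contributed by WPBs with a Feret
  diameter above the length cut (1.5 um);
* ``TotalWPBnrPerCellNR`` — WPBs per cell;
* ``TotalWPBrawIntDenPerCellNR`` — summed raw integrated WPB intensity per
  cell;
* ``TotalFoVpercentWPBnr`` — number fraction of WPBs above the length cut.

Plate normalization follows the B-score procedure: a two-way median polish
removes additive row and column (positional) effects, and residuals are
scaled by their MAD (consistency constant 1.4826). Wells are then scored
robustly against the sample-well distribution (Z scores), assay quality is
summarized by the Z' factor of the control separation, and reproducibility
by the per-well standard deviation across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, ParameterError

__all__ = [
    "WELL_FEATURES",
    "WellFeatureVector",
    "compute_well_features",
    "median_polish",
    "b_score_normalize",
    "z_scores",
    "z_prime",
    "replicate_sd",
    "hit_list",
]

logger = logging.getLogger(__name__)

#: Canonical feature order and the folder names used for screen input files.
WELL_FEATURES = [
    "PercentWPBarea",
    "TotalWPBnrPerCellNR",
    "TotalWPBrawIntDenPerCellNR",
    "TotalFoVpercentWPBnr",
]
FEATURE_FOLDERS = {
    "PercentWPBarea": "1_PercentWPBarea",
    "TotalWPBnrPerCellNR": "2_TotalWPBnrPerCellNR",
    "TotalWPBrawIntDenPerCellNR": "3_TotalWPBrawIntDenPerCellNR",
    "TotalFoVpercentWPBnr": "4_TotalFoVpercentWPBnr",
}

MAD_CONSTANT = 1.4826


@dataclass
class WellFeatureVector:
    """The four per-well statistics plus bookkeeping.

    ``n_fov_used`` maps each feature to the number of fields that entered
    its mean: a field with zero WPBs carries no information about the
    length-fraction features (0/0) and a field with zero cells none about
    the per-cell features, so such fields are excluded rather than counted
    as zero.
    """

    well: str
    plate: str = ""
    PercentWPBarea: float = np.nan
    TotalWPBnrPerCellNR: float = np.nan
    TotalWPBrawIntDenPerCellNR: float = np.nan
    TotalFoVpercentWPBnr: float = np.nan
    n_fov_used: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"plate": self.plate, "well": self.well}
        d.update({f: getattr(self, f) for f in WELL_FEATURES})
        return d


def compute_well_features(
    feature_tables: list[pd.DataFrame],
    cell_counts: list[int],
    feret_cut_um: float = 1.5,
    well: str = "",
    plate: str = "",
) -> WellFeatureVector:
    """Per-well feature vector from the per-FoV object tables.

    Each element of ``feature_tables`` is one field's WPB table (needs the
    ``Area``, ``Feret`` and ``RawIntDen`` columns); ``cell_counts`` gives
    the number of cells per field. The length cut is strict
    (``Feret > feret_cut_um``). A well where every field is degenerate for
    a feature gets NaN for it (logged).
    """
    if len(feature_tables) != len(cell_counts):
        raise ParameterError("one cell count per field of view is required")
    if not feature_tables:
        raise ParameterError("at least one field of view is required")
    f1, f2, f3, f4 = [], [], [], []
    for tab, n_cells in zip(feature_tables, cell_counts):
        n_wpb = len(tab)
        if n_wpb > 0:
            over = tab["Feret"] > feret_cut_um
            f1.append(float(tab.loc[over, "Area"].sum() / tab["Area"].sum()))
            f4.append(float(over.sum() / n_wpb))
        if n_cells > 0:
            f2.append(n_wpb / n_cells)
            f3.append(float(tab["RawIntDen"].sum()) / n_cells)
    vec = WellFeatureVector(well=well, plate=plate)
    for name, vals in zip(WELL_FEATURES, (f1, f2, f3, f4)):
        vec.n_fov_used[name] = len(vals)
        if vals:
            setattr(vec, name, float(np.mean(vals)))
        else:
            logger.warning("well %s: no usable field of view for %s", well, name)
    return vec


def median_polish(
    x: np.ndarray, max_iter: int = 2000, tol: float = 1e-9
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Two-way median polish of a plate matrix (NaNs allowed).

    Alternately sweeps row and column medians out of the residuals until
    the total absolute adjustment per iteration falls below ``tol`` or
    ``max_iter`` iterations are reached; the defaults run the polish to
    numerical convergence so residuals match an indefinitely iterated
    polish to well below 1e-6. Returns
    ``(overall, row_effects, col_effects, residuals)``.
    """
    x = np.asarray(x, dtype=float)
    if np.all(np.isnan(x)):
        raise ParameterError("median polish of an all-missing plate")
    resid = x.copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    with np.errstate(all="ignore"):
        for _ in range(max_iter):
            rdelta = np.nanmedian(resid, axis=1)
            rdelta = np.where(np.isnan(rdelta), 0.0, rdelta)
            resid -= rdelta[:, None]
            row += rdelta
            cshift = np.median(col)
            col -= cshift
            overall += cshift
            cdelta = np.nanmedian(resid, axis=0)
            cdelta = np.where(np.isnan(cdelta), 0.0, cdelta)
            resid -= cdelta[None, :]
            col += cdelta
            rshift = np.median(row)
            row -= rshift
            overall += rshift
            change = np.abs(rdelta).sum() + np.abs(cdelta).sum()
            if change < tol:
                break
    return overall, row, col, resid


def b_score_normalize(plate: np.ndarray, max_iter: int = 2000, tol: float = 1e-9) -> np.ndarray:
    """B scores of a plate matrix: median-polish residuals scaled by their
    MAD (times 1.4826).

    An exactly additive plate has zero residuals and zero MAD; the 0/0 is
    resolved to all-zero B scores. NaN wells stay NaN.
    """
    _, _, _, resid = median_polish(plate, max_iter=max_iter, tol=tol)
    mad = np.nanmedian(np.abs(resid))
    if not np.isfinite(mad) or mad == 0:
        out = np.zeros_like(resid)
        out[np.isnan(resid)] = np.nan
        return out
    return resid / (MAD_CONSTANT * mad)


def z_scores(values: pd.Series, roles: pd.Series) -> pd.Series:
    """Robust Z scores with location and scale from sample wells only:
    ``z = (x - median(samples)) / (1.4826 * MAD(samples))``.

    ``values`` and ``roles`` must be aligned; roles are 'sample',
    'negative_control' or 'positive_control'. Raises
    :class:`DegenerateScaleError` when the sample MAD is zero.
    """
    values = pd.Series(values)
    roles = pd.Series(roles)
    samples = values[roles.values == "sample"].dropna()
    if samples.nunique() < 2:
        raise DegenerateScaleError("need >= 2 distinct sample values for Z scoring")
    med = float(samples.median())
    mad = float((samples - med).abs().median())
    if mad == 0:
        raise DegenerateScaleError("sample MAD is zero; Z scores undefined")
    return (values - med) / (MAD_CONSTANT * mad)


def z_prime(pos: np.ndarray, neg: np.ndarray) -> float:
    """Z' factor of the control separation:
    ``1 - 3 (sd_pos + sd_neg) / |mean_pos - mean_neg|`` with sample SDs.

    Values near 1 indicate an excellent assay window; <= 0 overlapping
    controls. Raises :class:`ParameterError` for fewer than two values per
    group and :class:`DegenerateScaleError` for equal means.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ParameterError("Z' requires >= 2 values per control group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise DegenerateScaleError("control means are equal; Z' undefined")
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / abs(mu_p - mu_n)


def replicate_sd(replicates: list[np.ndarray]) -> np.ndarray:
    """Per-well sample standard deviation across aligned replicate plates."""
    if len(replicates) < 2:
        raise ParameterError("replicate SD requires >= 2 replicates")
    stack = np.stack([np.asarray(r, dtype=float) for r in replicates])
    if any(r.shape != stack[0].shape for r in stack):
        raise ParameterError("replicate plates differ in shape")
    return stack.std(axis=0, ddof=1)


def hit_list(
    z: pd.Series,
    roles: pd.Series,
    threshold: float = 2.0,
    annotations: dict | None = None,
) -> pd.DataFrame:
    """Sample wells with ``z > threshold`` (strict), ranked descending.

    ``z`` is indexed by well identifier (or (plate, well)); ``annotations``
    optionally maps the index to gene symbols.
    """
    z = pd.Series(z)
    roles = pd.Series(roles)
    sel = (roles.values == "sample") & (z.values > threshold)
    hits = z[sel].sort_values(ascending=False)
    out = pd.DataFrame({"well": hits.index, "z_score": hits.values})
    if annotations:
        out["gene"] = [annotations.get(w, "") for w in hits.index]
    return out.reset_index(drop=True)
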