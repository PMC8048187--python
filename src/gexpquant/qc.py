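"""Quality-control analyses: mixing linearity, replicate concordance, display.

Three checks mirror how a multiplex RT-PCR assay is validated in practice:

* *mixing linearity* — when two RNA pools are mixed at varying ratios, each
  gene's NPA should be a straight-line function of the mixing fraction
  (co-amplification independence); a near-zero R² marks a gene whose
  abundance does not differ between the pools.
* *replicate concordance* — the log2 ratio between two independent
  measurements of the same sample, histogrammed after centering the modal
  bin at zero; values below the detection limit are excluded.
* *max-normalization* — scaling a per-gene time series to its maximum for
  comparative display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySummaryError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "mixing_linearity",
    "ConcordanceSummary",
    "replicate_concordance",
    "NormalizedSeries",
    "normalize_timeseries",
]

DEFAULT_BIN_WIDTH = 0.2  # log2 units


def mixing_linearity(design: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    """Per-gene straight-line fit of NPA versus mixing fraction (linear axes).

    ``design`` has one row per (ratio, gene) with columns ``ratio``
    (fraction of pool A in the mix, 0..1), ``gene_id`` and ``npa``.
    Returns per gene: slope, intercept, r_squared, n_points.  The slope's
    sign classifies the regulation direction relative to the axis
    convention; genes with fewer than ``min_points`` usable ratios are
    skipped with a warning.
    """
    required = {"ratio", "gene_id", "npa"}
    missing = required - set(design.columns)
    if missing:
        raise InvalidParameterError(f"mixing design missing columns {sorted(missing)}")
    ratios = design["ratio"].to_numpy(dtype=float)
    if ((ratios < 0) | (ratios > 1)).any():
        raise InvalidParameterError("mixing ratios must lie in [0, 1]")
    if design["ratio"].nunique() < 3:
        raise InvalidParameterError("need >= 3 distinct mixing ratios")
    rows = []
    for gene_id, sub in design.groupby("gene_id", sort=False):
        usable = sub.dropna(subset=["npa"])
        if usable["ratio"].nunique() < min_points:
            logger.warning("%s: fewer than %d usable ratios, skipped", gene_id, min_points)
            continue
        x = usable["ratio"].to_numpy(dtype=float)
        y = usable["npa"].to_numpy(dtype=float)
        fit = stats.linregress(x, y)
        # a flat (non-regulated) gene has no NPA response to the mix ratio;
        # scipy reports r = nan there, which we record as R^2 = 0
        r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
        rows.append(
            {
                "gene_id": str(gene_id),
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r_squared": r2,
                "n_points": len(x),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "slope", "intercept", "r_squared", "n_points"])


@dataclass
class ConcordanceSummary:
    """Technical-replicate concordance of paired expression measurements.

    ``log2_ratios`` are the raw per-pair log2(value_1/value_2);
    ``mode_shift`` is the offset subtracted so the modal histogram bin is
    centered at 0.  Fractions are computed on the shifted values with
    inclusive boundaries: within two-fold means |log2| <= 1 and beyond
    four-fold |log2| >= 2.  The un-centered fractions are retained as
    ``raw_frac_*`` alongside.
    """

    log2_ratios: np.ndarray
    bin_width: float
    mode_shift: float
    frac_within_2fold: float
    frac_beyond_4fold: float
    raw_frac_within_2fold: float
    raw_frac_beyond_4fold: float
    n_used: int
    n_excluded: int
    histogram: pd.DataFrame = field(repr=False, default=None)  # bin_center, count

    @property
    def centered_ratios(self) -> np.ndarray:
        return self.log2_ratios - self.mode_shift


def _mode_center(ratios: np.ndarray, bin_width: float) -> float:
    """Center of the most populated bin on a grid of bins centered at k*bin_width.

    Ties are broken toward the bin closest to zero, so exact data never get
    an arbitrary shift.
    """
    idx = np.round(ratios / bin_width).astype(int)
    counts: dict[int, int] = {}
    for k in idx:
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.items(), key=lambda kv: (kv[1], -abs(kv[0])))
    return best[0] * bin_width


def replicate_concordance(
    pairs: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> ConcordanceSummary:
    """Summarize agreement between two independent measurements per sample/gene.

    ``pairs`` has columns ``value_1`` and ``value_2`` (relative amounts)
    and optional boolean ``below_limit_1`` / ``below_limit_2``; a pair with
    either value below the detection limit is excluded and counted in
    ``n_excluded``.  The log2-ratio distribution is shifted so its modal
    bin sits at zero before the two-fold / four-fold fractions are taken.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    required = {"value_1", "value_2"}
    if required - set(pairs.columns):
        raise InvalidParameterError("pairs need 'value_1' and 'value_2' columns")
    v1 = pairs["value_1"].to_numpy(dtype=float)
    v2 = pairs["value_2"].to_numpy(dtype=float)
    excluded = ~np.isfinite(v1) | ~np.isfinite(v2) | (v1 <= 0) | (v2 <= 0)
    for col in ("below_limit_1", "below_limit_2"):
        if col in pairs.columns:
            excluded |= pairs[col].to_numpy(dtype=bool)
    usable = ~excluded
    if not usable.any():
        raise EmptySummaryError("no replicate pairs remain after exclusions")
    ratios = np.log2(v1[usable] / v2[usable])
    shift = _mode_center(ratios, bin_width)
    centered = ratios - shift

    def _fractions(values: np.ndarray) -> tuple[float, float]:
        within = float(np.mean(np.abs(values) <= 1.0))
        beyond = float(np.mean(np.abs(values) >= 2.0))
        return within, beyond

    frac_within, frac_beyond = _fractions(centered)
    raw_within, raw_beyond = _fractions(ratios)
    lo = np.floor(centered.min() / bin_width - 0.5)
    hi = np.ceil(centered.max() / bin_width + 0.5)
    edges = (np.arange(lo, hi + 1) + 0.5) * bin_width
    counts, edges = np.histogram(centered, bins=edges)
    hist = pd.DataFrame(
        {"bin_center": (edges[:-1] + edges[1:]) / 2.0, "count": counts}
    )
    return ConcordanceSummary(
        log2_ratios=ratios,
        bin_width=bin_width,
        mode_shift=shift,
        frac_within_2fold=frac_within,
        frac_beyond_4fold=frac_beyond,
        raw_frac_within_2fold=raw_within,
        raw_frac_beyond_4fold=raw_beyond,
        n_used=int(usable.sum()),
        n_excluded=int(excluded.sum()),
        histogram=hist,
    )


class NormalizedSeries(NamedTuple):
    """Max-normalized expression time series with below-limit entries preserved."""

    fractions: np.ndarray  # NaN where below limit
    below_limit: np.ndarray


def normalize_timeseries(
    values: Sequence[float],
    below_limit: Optional[Sequence[bool]] = None,
) -> NormalizedSeries:
    """Scale a per-gene time series to its maximum quantifiable value.

    Below-limit entries stay flagged (and NaN in the output) rather than
    being treated as zero.  A series with no quantifiable positive value
    cannot be normalized and raises :class:`EmptySummaryError`.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise InvalidParameterError("values must be a non-empty 1-D sequence")
    mask = (
        np.zeros(len(v), dtype=bool)
        if below_limit is None
        else np.asarray(below_limit, dtype=bool)
    )
    if mask.shape != v.shape:
        raise InvalidParameterError("below_limit mask must match values in length")
    mask = mask | ~np.isfinite(v)
    usable = v[~mask]
    if len(usable) == 0 or np.nanmax(usable) <= 0:
        raise EmptySummaryError("series has no quantifiable positive value")
    peak = float(np.max(usable))
    fractions = np.where(mask, np.nan, v / peak)
    return NormalizedSeries(fractions=fractions, below_limit=mask)
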