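"""Shared-slope calibration over log-log dilution series and back-calculation.

The calibration procedure is two-stage.  For each gene *i*, the normalized
peak areas F_i measured over a total-RNA dilution series are fitted on a
double-logarithmic (base-10) plot::

    log F_i = a_i * log [RNA]_tot + b_i          (1st regression)

The per-gene slopes a_i are then averaged into a common slope ā — the
kinetic model predicts parallel lines, so a single slope is the correct
pooled estimate — and each gene's intercept is refit at that shared slope::

    b_{i,ā} = mean(log F_i) - ā * mean(log [RNA]_tot)   (2nd regression)

which is the least-squares-optimal intercept for a fixed slope.  A sample's
relative transcript amount is then read off the inverted line::

    [RNA]_i^rel = 10**A,   A = (log10 F_i - b_{i,ā}) / ā

Detection limits map a run's NPA floor (smallest trustworthy peak area
divided by the spike-in area, or a fixed NPA) through the same line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFitError,
    InvalidParameterError,
    NormalizationError,
    UnknownGeneError,
)
from .fragments import GenePanel, SeparationRun, assign_fragments

logger = logging.getLogger(__name__)

__all__ = [
    "DilutionSeries",
    "GeneFit",
    "FloorPolicy",
    "CalibrationModel",
    "fit_gene",
    "build_model",
    "quantify",
    "detection_limit",
    "run_npa_floor",
    "write_model",
    "read_model",
]


@dataclass
class DilutionSeries:
    """NPA measurements over a total-RNA dilution series.

    ``data`` holds one row per (sample, gene) with at least the columns
    ``total_rna_ng``, ``gene_id``, ``npa``; an optional ``below_floor``
    column marks unquantifiable entries and an optional ``sample_id``
    distinguishes replicate measurements of the same concentration.
    """

    data: pd.DataFrame
    series_id: str = "series"

    def __post_init__(self) -> None:
        required = {"total_rna_ng", "gene_id", "npa"}
        missing = required - set(self.data.columns)
        if missing:
            raise InvalidParameterError(f"dilution series missing columns {sorted(missing)}")
        concs = self.data["total_rna_ng"].dropna().unique()
        if (concs <= 0).any():
            raise InvalidParameterError("total_rna_ng values must be > 0")
        if len(concs) < 2:
            raise DegenerateFitError(
                "a dilution series needs >= 2 distinct total-RNA concentrations"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene_id"].unique())


@dataclass
class GeneFit:
    """Per-gene calibration fit: first-regression line plus shared intercept."""

    gene_id: str
    slope_a: float
    intercept_b: float
    r_squared: float
    n_points: int
    shared_intercept: Optional[float] = None


@dataclass(frozen=True)
class FloorPolicy:
    """How the per-run NPA quantification floor is derived.

    Default: a minimum trustworthy peak area (instrument noise floor, in
    the same fluorescence units as the tables) divided by the run's
    spike-in area.  Setting ``fixed_npa`` uses that NPA for every run
    instead.
    """

    min_peak_area: float = 50.0
    fixed_npa: Optional[float] = None

    def npa_floor(self, spike_area: Optional[float]) -> float:
        if self.fixed_npa is not None:
            if self.fixed_npa <= 0:
                raise InvalidParameterError("fixed_npa must be > 0")
            return self.fixed_npa
        if spike_area is None or spike_area <= 0:
            raise NormalizationError(
                "area-based floor policy needs a positive spike-in area"
            )
        return self.min_peak_area / spike_area


@dataclass
class CalibrationModel:
    """Shared-slope calibration model for a gene panel.

    ``mean_slope`` is the unweighted arithmetic mean of the per-gene
    first-regression slopes; each :class:`GeneFit` carries both its own
    line and the shared-slope intercept.  ``detection_limits`` maps
    gene_id -> (npa_floor, rel_amount_limit) at the model's reference
    floor; per-run limits are recomputed via :func:`detection_limit`.
    """

    mean_slope: float
    fits: dict[str, GeneFit]
    detection_limits: dict[str, tuple[float, float]] = field(default_factory=dict)
    floor_policy: FloorPolicy = field(default_factory=FloorPolicy)
    replicate_mode: str = "points"
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def max_abs_slope_dev(self) -> float:
        """Parallelism diagnostic: max |a_i - ā| over genes."""
        return max(abs(f.slope_a - self.mean_slope) for f in self.fits.values())

    def gene_fit(self, gene_id: str) -> GeneFit:
        try:
            return self.fits[gene_id]
        except KeyError:
            raise UnknownGeneError(f"gene {gene_id!r} not in calibration model") from None

    def rel_amount(self, gene_id: str, npa: float) -> float:
        """Invert the calibration line: 10**((log10 F - b_{i,ā}) / ā)."""
        fit = self.gene_fit(gene_id)
        if npa <= 0:
            raise InvalidParameterError("npa must be > 0 to invert the log-domain line")
        a_bar = self.mean_slope
        exponent = (np.log10(npa) - fit.shared_intercept) / a_bar
        return float(10.0 ** exponent)


def fit_gene(
    log_rna: Sequence[float],
    log_npa: Sequence[float],
    gene_id: str = "gene",
) -> GeneFit:
    """First linear regression: OLS of log10 NPA on log10 total RNA.

    Slope and intercept follow the covariance/variance form

        a = sum((x - x̄)(y - ȳ)) / sum((x - x̄)²),   b = ȳ - a x̄

    R² is the squared Pearson correlation of the fit (reported 1.0 when the
    response has zero variance, i.e. the flat line fits exactly).
    """
    x = np.asarray(log_rna, dtype=float)
    y = np.asarray(log_npa, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("log_rna and log_npa must be 1-D of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or len(np.unique(x)) < 2:
        raise DegenerateFitError(
            f"{gene_id}: need >= 2 points with distinct abscissae, have "
            f"{len(np.unique(x))}"
        )
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    sxy = float(np.sum(dx * dy))
    syy = float(np.sum(dy * dy))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = 1.0 if syy == 0.0 else min(1.0, (sxy * sxy) / (sxx * syy))
    return GeneFit(
        gene_id=gene_id,
        slope_a=slope,
        intercept_b=intercept,
        r_squared=r2,
        n_points=len(x),
    )


def _gene_points(
    sub: pd.DataFrame, replicate_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Log-domain (x, y) points for one gene, honouring the replicate mode."""
    if replicate_mode == "means":
        grouped = sub.groupby("total_rna_ng", sort=True)["npa"].mean()
        x = np.log10(grouped.index.to_numpy(dtype=float))
        y = np.log10(grouped.to_numpy(dtype=float))
    elif replicate_mode == "points":
        x = np.log10(sub["total_rna_ng"].to_numpy(dtype=float))
        y = np.log10(sub["npa"].to_numpy(dtype=float))
    else:
        raise InvalidParameterError(f"unknown replicate_mode {replicate_mode!r}")
    return x, y


def build_model(
    series: DilutionSeries,
    replicate_mode: str = "points",
    floor_policy: FloorPolicy = FloorPolicy(),
    spike_gene_id: Optional[str] = None,
    drop_genes: Iterable[str] = (),
) -> CalibrationModel:
    """Build the shared-slope calibration model from a dilution series.

    Per gene: fit the 1st regression on all usable points (NPA > 0, not
    below floor); average the slopes (unweighted) into ā; refit every
    intercept at ā by the closed form ``b_{i,ā} = ȳ - ā x̄``, which is
    optimal in the least-squares sense for the fixed slope.  ``means``
    replicate mode averages NPAs per concentration before taking logs.

    The spike-in gene (NPA identically 1) carries no calibration
    information and is excluded from the slope average when identified via
    ``spike_gene_id``.  Unfittable genes abort the build, naming them, so
    the caller can drop them explicitly via ``drop_genes``.
    """
    drop = set(drop_genes)
    if spike_gene_id is not None:
        drop.add(spike_gene_id)
    fits: dict[str, GeneFit] = {}
    point_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    failures: list[str] = []
    for gene_id, sub in series.data.groupby("gene_id", sort=False):
        if gene_id in drop:
            continue
        usable = sub[sub["npa"] > 0]
        if "below_floor" in usable.columns:
            usable = usable[~usable["below_floor"].astype(bool)]
        n_dropped = len(sub) - len(usable)
        if n_dropped:
            logger.warning(
                "%s: %d non-positive/below-floor points excluded from calibration",
                gene_id,
                n_dropped,
            )
        try:
            x, y = _gene_points(usable, replicate_mode)
            fits[str(gene_id)] = fit_gene(x, y, gene_id=str(gene_id))
            point_cache[str(gene_id)] = (x, y)
        except DegenerateFitError:
            failures.append(str(gene_id))
    if failures:
        raise DegenerateFitError(
            "calibration model build failed; unfittable genes: " + ", ".join(failures)
        )
    if not fits:
        raise DegenerateFitError("no genes to calibrate")
    mean_slope = float(np.mean([f.slope_a for f in fits.values()]))
    for gene_id, fit in fits.items():
        x, y = point_cache[gene_id]
        fit.shared_intercept = float(y.mean() - mean_slope * x.mean())
    model = CalibrationModel(
        mean_slope=mean_slope,
        fits=fits,
        floor_policy=floor_policy,
        replicate_mode=replicate_mode,
        provenance={"series_id": series.series_id},
    )
    model.detection_limits = _reference_limits(series, model, spike_gene_id)
    return model


def _reference_limits(
    series: DilutionSeries,
    model: CalibrationModel,
    spike_gene_id: Optional[str],
) -> dict[str, tuple[float, float]]:
    """Model-level detection limits at the series' reference NPA floor."""
    spike_area: Optional[float] = None
    if model.floor_policy.fixed_npa is None:
        if spike_gene_id is not None and "peak_area" in series.data.columns:
            spike_rows = series.data[series.data["gene_id"] == spike_gene_id]
            areas = spike_rows["peak_area"].dropna()
            if len(areas):
                spike_area = float(areas.median())
        if spike_area is None:
            return {}
    floor = model.floor_policy.npa_floor(spike_area)
    return {
        gene_id: (floor, model.rel_amount(gene_id, floor)) for gene_id in model.fits
    }


def run_npa_floor(
    run: SeparationRun,
    panel: GenePanel,
    floor_policy: FloorPolicy = FloorPolicy(),
    tolerance_nt: float = 2.0,
) -> float:
    """NPA quantification floor of one separation run under a floor policy."""
    if floor_policy.fixed_npa is not None:
        return floor_policy.npa_floor(None)
    assignment = assign_fragments(run, panel, tolerance_nt)
    spike = assignment.get(panel.spike_in.gene_id)
    if spike is None or spike.peak_area <= 0:
        raise NormalizationError(
            f"run {run.run_id}: spike-in missing, cannot derive NPA floor"
        )
    return floor_policy.npa_floor(spike.peak_area)


def detection_limit(
    model: CalibrationModel,
    npa_floor: float,
    genes: Optional[Iterable[str]] = None,
) -> dict[str, float]:
    """Per-gene relative-amount detection limits at a given NPA floor.

    The floor maps through each gene's shared-slope line:
    ``limit = 10**((log10 floor - b_{i,ā}) / ā)``.  Monotone in the floor:
    doubling the floor multiplies every limit by ``2**(1/ā)``.
    """
    if npa_floor <= 0:
        raise InvalidParameterError("npa_floor must be > 0")
    gene_ids = list(genes) if genes is not None else list(model.fits)
    return {g: model.rel_amount(g, npa_floor) for g in gene_ids}


def quantify(
    npa_rows: pd.DataFrame,
    model: CalibrationModel,
    npa_floor: Optional[float] = None,
) -> pd.DataFrame:
    """Back-calculate relative transcript amounts from NPA rows.

    Input rows need ``gene_id`` and ``npa`` (extra columns such as
    ``sample_id``, ``matched_length_nt``, ``peak_area`` are carried
    through).  ``npa_floor`` overrides the model's stored reference floor;
    measurements at or below the floor (or with no matched fragment) are
    flagged ``below_limit`` and their ``rel_amount`` reported as the limit
    value, never as zero.
    """
    if "gene_id" not in npa_rows.columns or "npa" not in npa_rows.columns:
        raise InvalidParameterError("npa rows need 'gene_id' and 'npa' columns")
    out = npa_rows.copy()
    rel = np.full(len(out), np.nan)
    limit = np.full(len(out), np.nan)
    below = np.zeros(len(out), dtype=bool)
    for pos, row in enumerate(out.itertuples(index=False)):
        gene_id = str(row.gene_id)
        fit = model.gene_fit(gene_id)  # raises UnknownGeneError
        floor = npa_floor
        if floor is None and gene_id in model.detection_limits:
            floor = model.detection_limits[gene_id][0]
        gene_limit = model.rel_amount(gene_id, floor) if floor else np.nan
        limit[pos] = gene_limit
        npa = row.npa
        flagged = bool(getattr(row, "below_floor", False))
        if npa is None or not np.isfinite(npa) or npa <= 0 or flagged:
            below[pos] = True
            rel[pos] = gene_limit
        elif floor is not None and npa < floor:
            below[pos] = True
            rel[pos] = gene_limit
        else:
            rel[pos] = model.rel_amount(gene_id, float(npa))
    out["rel_amount"] = rel
    out["detection_limit"] = limit
    out["below_limit"] = below
    return out


# ---------------------------------------------------------------------------
# model (de)serialization: TSV body + structured '#' header
# ---------------------------------------------------------------------------

_MODEL_COLUMNS = (
    "gene_id",
    "slope_a",
    "intercept_b",
    "r_squared",
    "n_points",
    "shared_intercept",
    "npa_floor",
    "rel_amount_limit",
)


def write_model(model: CalibrationModel, path: str | Path) -> None:
    """Serialize a calibration model so a kit-specific standard curve can be reused."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("# gexpquant calibration model v1\n")
        fh.write(f"# mean_slope\t{model.mean_slope!r}\n")
        fh.write(f"# replicate_mode\t{model.replicate_mode}\n")
        fh.write(f"# floor_min_peak_area\t{model.floor_policy.min_peak_area!r}\n")
        fh.write(f"# floor_fixed_npa\t{model.floor_policy.fixed_npa!r}\n")
        for key, value in sorted(model.provenance.items()):
            fh.write(f"# provenance\t{key}\t{value}\n")
        fh.write("\t".join(_MODEL_COLUMNS) + "\n")
        for gene_id in sorted(model.fits):
            f = model.fits[gene_id]
            floor, lim = model.detection_limits.get(gene_id, (np.nan, np.nan))
            fh.write(
                f"{gene_id}\t{f.slope_a!r}\t{f.intercept_b!r}\t{f.r_squared!r}\t"
                f"{f.n_points}\t{f.shared_intercept!r}\t{floor!r}\t{lim!r}\n"
            )


def read_model(path: str | Path) -> CalibrationModel:
    """Load a calibration model written by :func:`write_model` (exact round-trip)."""
    path = Path(path)
    header: dict[str, str] = {}
    provenance: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        parts = line[1:].strip().split("\t")
        if parts[0] == "provenance" and len(parts) >= 3:
            provenance[parts[1]] = parts[2]
        elif len(parts) == 2:
            header[parts[0]] = parts[1]
    from io import StringIO

    df = pd.read_csv(
        StringIO("".join(lines[body_start:])), sep="\t", float_precision="round_trip"
    )
    missing = set(_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{path}: model file missing columns {sorted(missing)}")
    fits: dict[str, GeneFit] = {}
    limits: dict[str, tuple[float, float]] = {}
    for r in df.itertuples(index=False):
        gene_id = str(r.gene_id)
        fits[gene_id] = GeneFit(
            gene_id=gene_id,
            slope_a=float(r.slope_a),
            intercept_b=float(r.intercept_b),
            r_squared=float(r.r_squared),
            n_points=int(r.n_points),
            shared_intercept=float(r.shared_intercept),
        )
        if np.isfinite(r.npa_floor):
            limits[gene_id] = (float(r.npa_floor), float(r.rel_amount_limit))
    fixed = header.get("floor_fixed_npa", "None")
    policy = FloorPolicy(
        min_peak_area=float(header.get("floor_min_peak_area", 50.0)),
        fixed_npa=None if fixed == "None" else float(fixed),
    )
    return CalibrationModel(
        mean_slope=float(header["mean_slope"]),
        fits=fits,
        detection_limits=limits,
        floor_policy=policy,
        replicate_mode=header.get("replicate_mode", "points"),
        provenance=provenance,
    )
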