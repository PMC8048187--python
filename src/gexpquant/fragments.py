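"""Capillary-electrophoresis fragment tables: parsing, gene assignment, NPA.

A separation run yields one table row per detected peak (fragment index,
sized length in nucleotides, peak height, peak area).  Peaks are assigned
to panel genes by nearest expected fragment length within a tolerance, and
peak areas are normalized to the spike-in fragment's area of the same run
to give the normalized peak area (NPA) — the relative fluorescence signal
F_i that all downstream calibration works on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousAssignmentError,
    ConfigurationError,
    FragmentTableError,
    InvalidParameterError,
    NormalizationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentRecord",
    "SeparationRun",
    "PanelEntry",
    "GenePanel",
    "FRAGMENT_COLUMNS",
    "read_fragment_table",
    "write_fragment_table",
    "read_panel",
    "write_panel",
    "assign_fragments",
    "normalize_run",
    "DEFAULT_TOLERANCE_NT",
]

#: canonical tab-separated fragment-table columns
FRAGMENT_COLUMNS = ("fragment_index", "length_nt", "peak_height", "peak_area")

#: default length-matching tolerance; ladder sizing is sub-nucleotide but fractional
DEFAULT_TOLERANCE_NT = 2.0


@dataclass(frozen=True)
class FragmentRecord:
    """One detected electrophoresis peak."""

    fragment_index: int
    length_nt: float
    peak_height: float
    peak_area: float

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise InvalidParameterError(f"length_nt must be > 0, got {self.length_nt}")
        if self.peak_height < 0 or self.peak_area < 0:
            raise InvalidParameterError("peak height/area must be >= 0")


@dataclass
class SeparationRun:
    """All fragments detected in one capillary separation of one sample."""

    run_id: str
    sample_id: str
    fragments: list[FragmentRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        indices = [f.fragment_index for f in self.fragments]
        if len(indices) != len(set(indices)):
            raise InvalidParameterError(
                f"run {self.run_id}: fragment_index values must be unique"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f.fragment_index, f.length_nt, f.peak_height, f.peak_area)
                for f in self.fragments
            ],
            columns=list(FRAGMENT_COLUMNS),
        )


@dataclass(frozen=True)
class PanelEntry:
    """One gene of the multiplex panel."""

    gene_id: str
    expected_length_nt: int
    is_spike_in: bool = False
    rt_primer_conc_um: float = 0.05  # attenuated stock concentration, uM

    def __post_init__(self) -> None:
        if self.expected_length_nt <= 0:
            raise InvalidParameterError("expected_length_nt must be > 0")
        if self.rt_primer_conc_um <= 0:
            raise InvalidParameterError("rt_primer_conc_um must be > 0")


@dataclass
class GenePanel:
    """The gene panel: expected fragment lengths and the spike-in flag.

    Exactly one entry must be the spike-in internal standard and expected
    lengths must be pairwise distinct so that fragments are assignable.
    """

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        spikes = [e for e in self.entries if e.is_spike_in]
        if len(spikes) != 1:
            raise InvalidParameterError(
                f"panel must contain exactly one spike-in entry, found {len(spikes)}"
            )
        lengths = [e.expected_length_nt for e in self.entries]
        if len(lengths) != len(set(lengths)):
            raise InvalidParameterError("expected fragment lengths must be distinct")
        ids = [e.gene_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise InvalidParameterError("gene_id values must be unique within a panel")

    @property
    def spike_in(self) -> PanelEntry:
        return next(e for e in self.entries if e.is_spike_in)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def min_length_spacing(self) -> float:
        lengths = sorted(e.expected_length_nt for e in self.entries)
        if len(lengths) < 2:
            return float("inf")
        return float(min(b - a for a, b in zip(lengths, lengths[1:])))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def read_fragment_table(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    run_id: Optional[str] = None,
    sample_id: Optional[str] = None,
) -> SeparationRun:
    """Read a tab-separated fragment table into a :class:`SeparationRun`.

    ``dialect`` maps alternative column names in the file onto the
    canonical ones (e.g. ``{"size_nt": "length_nt"}``).  Rows that fail
    numeric parsing or carry negative areas are rejected with a logged
    warning naming the line; a missing mandatory column is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FragmentTableError(f"fragment table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FragmentTableError(f"{path}: empty fragment table") from None
    if dialect:
        df = df.rename(columns=dict(dialect))
    for col in FRAGMENT_COLUMNS:
        if col not in df.columns:
            raise FragmentTableError(f"{path}: missing mandatory column '{col}'")
    records: list[FragmentRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        raw = {c: getattr(row, c) for c in FRAGMENT_COLUMNS}
        try:
            rec = FragmentRecord(
                fragment_index=int(raw["fragment_index"]),
                length_nt=float(raw["length_nt"]),
                peak_height=float(raw["peak_height"]),
                peak_area=float(raw["peak_area"]),
            )
        except (TypeError, ValueError, InvalidParameterError) as exc:
            logger.warning("%s: line %d rejected (%s)", path, pos, exc)
            continue
        records.append(rec)
    stem = path.stem
    return SeparationRun(
        run_id=run_id or stem,
        sample_id=sample_id or stem,
        fragments=records,
    )


def write_fragment_table(run: SeparationRun, path: str | Path) -> None:
    """Write a run in the canonical tab-separated dialect (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("\t".join(FRAGMENT_COLUMNS) + "\n")
        for f in run.fragments:
            fh.write(
                f"{f.fragment_index}\t{f.length_nt!r}\t{f.peak_height!r}\t{f.peak_area!r}\n"
            )


def read_panel(path: str | Path) -> GenePanel:
    """Read a panel definition TSV: gene_id, expected_length_nt, is_spike_in, rt_primer_conc_um."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (FileNotFoundError, pd.errors.EmptyDataError) as exc:
        raise FragmentTableError(f"cannot read panel {path}: {exc}") from None
    required = {"gene_id", "expected_length_nt", "is_spike_in", "rt_primer_conc_um"}
    missing = required - set(df.columns)
    if missing:
        raise FragmentTableError(f"{path}: panel missing columns {sorted(missing)}")
    entries = [
        PanelEntry(
            gene_id=str(r.gene_id),
            expected_length_nt=int(r.expected_length_nt),
            is_spike_in=bool(r.is_spike_in),
            rt_primer_conc_um=float(r.rt_primer_conc_um),
        )
        for r in df.itertuples(index=False)
    ]
    return GenePanel(entries)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("gene_id\texpected_length_nt\tis_spike_in\trt_primer_conc_um\n")
        for e in panel.entries:
            fh.write(
                f"{e.gene_id}\t{e.expected_length_nt}\t{int(e.is_spike_in)}\t"
                f"{e.rt_primer_conc_um!r}\n"
            )


def assign_fragments(
    run: SeparationRun,
    panel: GenePanel,
    tolerance_nt: float = DEFAULT_TOLERANCE_NT,
) -> dict[str, Optional[FragmentRecord]]:
    """Match each panel gene to the nearest-length fragment within tolerance.

    Genes with no fragment within ``tolerance_nt`` map to ``None`` (the
    transcript was absent or below the instrument floor).  A fragment may
    serve at most one gene.  The tolerance must stay below half the minimum
    spacing of expected lengths, which also guarantees the assignment is
    independent of fragment order.  Equidistant candidates are resolved
    toward the larger peak area (peak-splitting artifact), with a log note.
    """
    if tolerance_nt <= 0:
        raise ConfigurationError("tolerance_nt must be > 0")
    half_spacing = panel.min_length_spacing() / 2.0
    if tolerance_nt >= half_spacing:
        raise ConfigurationError(
            f"tolerance_nt={tolerance_nt} must be < half the minimum expected-length "
            f"spacing ({half_spacing})"
        )
    assignment: dict[str, Optional[FragmentRecord]] = {}
    claimed: dict[int, str] = {}
    for entry in panel:
        candidates = [
            f for f in run.fragments if abs(f.length_nt - entry.expected_length_nt) <= tolerance_nt
        ]
        if not candidates:
            assignment[entry.gene_id] = None
            continue
        # deterministic under permutation: distance, then larger area, then index
        candidates.sort(
            key=lambda f: (
                abs(f.length_nt - entry.expected_length_nt),
                -f.peak_area,
                f.fragment_index,
            )
        )
        if (
            len(candidates) > 1
            and abs(candidates[0].length_nt - entry.expected_length_nt)
            == abs(candidates[1].length_nt - entry.expected_length_nt)
        ):
            logger.info(
                "%s: equidistant fragments for gene %s; larger-area peak %d chosen",
                run.run_id,
                entry.gene_id,
                candidates[0].fragment_index,
            )
        chosen = candidates[0]
        if chosen.fragment_index in claimed:
            raise AmbiguousAssignmentError(
                f"fragment {chosen.fragment_index} ({chosen.length_nt} nt) claimed by "
                f"both {claimed[chosen.fragment_index]} and {entry.gene_id}"
            )
        claimed[chosen.fragment_index] = entry.gene_id
        assignment[entry.gene_id] = chosen
    return assignment


def normalize_run(
    run: SeparationRun,
    panel: GenePanel,
    assignment: Optional[dict[str, Optional[FragmentRecord]]] = None,
    tolerance_nt: float = DEFAULT_TOLERANCE_NT,
) -> pd.DataFrame:
    """Spike-in-normalized peak areas (NPA) for one run.

    Returns one row per panel gene with columns ``sample_id, run_id,
    gene_id, matched_length_nt, peak_area, npa, below_floor``.  NPA is the
    gene's peak area divided by the spike-in's peak area of the same run,
    so the spike-in's own NPA is 1 and rescaling the whole run cancels.
    Genes without a matched fragment carry ``npa = NaN`` and
    ``below_floor = True`` so log-domain math never receives a zero.
    """
    if assignment is None:
        assignment = assign_fragments(run, panel, tolerance_nt)
    spike = assignment.get(panel.spike_in.gene_id)
    if spike is None or spike.peak_area <= 0:
        raise NormalizationError(
            f"run {run.run_id}: spike-in fragment missing or has zero area; "
            "run is unusable"
        )
    rows = []
    for entry in panel:
        frag = assignment.get(entry.gene_id)
        if frag is None:
            rows.append(
                {
                    "sample_id": run.sample_id,
                    "run_id": run.run_id,
                    "gene_id": entry.gene_id,
                    "fragment_index": pd.NA,
                    "matched_length_nt": np.nan,
                    "peak_area": np.nan,
                    "npa": np.nan,
                    "below_floor": True,
                }
            )
        else:
            rows.append(
                {
                    "sample_id": run.sample_id,
                    "run_id": run.run_id,
                    "gene_id": entry.gene_id,
                    "fragment_index": frag.fragment_index,
                    "matched_length_nt": frag.length_nt,
                    "peak_area": frag.peak_area,
                    "npa": frag.peak_area / spike.peak_area,
                    "below_floor": False,
                }
            )
    return pd.DataFrame(rows)
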