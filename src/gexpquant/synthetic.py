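"""Seedable synthetic GeXP datasets with the statistical structure the method assumes.

The generator emulates what the capillary sequencer hands downstream: one
fragment table per separation run, with peak areas produced by the forward
kinetic model (per-gene transcript abundance x primer-limited RT x PCR
amplification x detector gain), a constant spike-in fragment per run, a
per-run global scale factor (pipetting / injection variability), and
multiplicative lognormal noise on areas plus Gaussian jitter on sized
lengths.  Peaks falling under the instrument's detection area are simply
absent from the table, the way an undetected peak would be.

Everything is deterministic given a seed, and every emitted table parses
through :mod:`gexpquant.fragments` at the default matching tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .fragments import (
    FragmentRecord,
    GenePanel,
    PanelEntry,
    SeparationRun,
    normalize_run,
    write_fragment_table,
    write_panel,
)
from .kinetics import (
    PCRSpec,
    Regulation,
    amplified_cdna,
    final_primer_concentration,
)

__all__ = [
    "SyntheticPanelSpec",
    "NoiseSpec",
    "SyntheticAssay",
    "generate_dilution_series",
    "generate_mixing_series",
    "generate_replicate_timeseries",
    "write_dataset",
    "DEFAULT_DILUTIONS_NG",
]

#: two-fold dilution series from 100 ng down to 0.78125 ng per reaction
DEFAULT_DILUTIONS_NG = tuple(100.0 / 2**k for k in range(8))

SPIKE_GENE_ID = "KANr"


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Design of a synthetic multiplex panel.

    Defaults mirror a realistic 35-gene assay: fragment lengths spread over
    114-357 nt, attenuated reverse-primer stocks between 0.00025 and
    0.5 uM, per-gene transcript abundances spanning two orders of magnitude
    around the femtomolar scale typical of single-gene mRNA in tens of
    nanograms of total RNA, and up-/down-/non-regulated genes for mixing
    and time-series designs.
    """

    n_genes: int = 35
    length_range_nt: tuple[int, int] = (114, 357)
    conc_range_m: tuple[float, float] = (1e-15, 1e-13)
    primer_stock_range_um: tuple[float, float] = (0.00025, 0.5)
    hybridization_rate: float = 1e6  # M^-1 s^-1
    rt_time_s: float = 3600.0
    frac_up: float = 0.3
    frac_down: float = 0.3
    fold_change: float = 4.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidParameterError("n_genes must be >= 1")
        if self.frac_up + self.frac_down > 1:
            raise InvalidParameterError("frac_up + frac_down must be <= 1")
        span = self.length_range_nt[1] - self.length_range_nt[0]
        if span < self.n_genes * 4:
            raise InvalidParameterError(
                "length range too narrow to keep fragments separable"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic separation runs.

    ``area_sigma`` is the standard deviation of the natural log of the
    multiplicative peak-area noise (0.05 = ~5% coefficient of variation);
    ``length_jitter_nt`` the Gaussian sigma of ladder-sizing error;
    ``run_scale_range`` the uniform range of the per-run global scale
    factor, which the spike-in normalization must cancel.
    """

    area_sigma: float = 0.05
    length_jitter_nt: float = 0.3
    run_scale_range: tuple[float, float] = (0.8, 1.25)

    def __post_init__(self) -> None:
        if self.area_sigma < 0 or self.length_jitter_nt < 0:
            raise InvalidParameterError("noise sigmas must be >= 0")
        if not 0 < self.run_scale_range[0] <= self.run_scale_range[1]:
            raise InvalidParameterError("invalid run_scale_range")

    @classmethod
    def none(cls) -> "NoiseSpec":
        """Noise-free measurements (for closing the loop with the kinetic model)."""
        return cls(area_sigma=0.0, length_jitter_nt=0.0, run_scale_range=(1.0, 1.0))


@dataclass
class SyntheticAssay:
    """A fully parameterized in-silico assay: panel plus kinetic ground truth.

    ``initial_conc`` holds each gene's transcript concentration at the
    reference input (100 ng total RNA); ``kprime`` the pseudo first-order
    RT rate constants.  ``gain`` converts molar amplified cDNA into
    fluorescence area units; peaks under ``detection_area`` go uncalled.
    """

    panel: GenePanel
    initial_conc: dict[str, float]
    kprime: dict[str, float]
    regulation: dict[str, Regulation]
    fold_change: dict[str, float]
    reaction_order: float = 1.0
    rt_time_s: float = 3600.0
    pcr: PCRSpec = field(default_factory=PCRSpec)
    gain: float = 1e9
    spike_area: float = 2e4
    detection_area: float = 10.0
    reference_input_ng: float = 100.0

    @classmethod
    def from_spec(
        cls,
        spec: SyntheticPanelSpec = SyntheticPanelSpec(),
        reaction_order: float = 1.0,
        seed: int = 0,
        kt_max: float = 0.05,
        kt_spread: float = 20.0,
    ) -> "SyntheticAssay":
        """Build an assay from a panel spec.

        For first-order RT (``reaction_order = 1``) concentrations are molar
        and k' comes directly from the primer concentrations; attenuation
        acts through the saturating factor ``1 - exp(-k't)``.  For
        ``reaction_order != 1`` the empirical power law is not
        scale-invariant, and at femtomolar concentrations it would exhaust
        every template instantly, which collapses back to first-order
        behaviour.  The observed slope-below-one regime is the
        low-conversion one, so the assay is then rescaled to dimensionless
        relative concentrations with ``k' * t`` spanning
        ``[kt_max/kt_spread, kt_max]`` across the attenuation range, keeping
        conversion partial at every dilution.
        """
        rng = np.random.default_rng(seed)
        n = spec.n_genes
        lo, hi = spec.length_range_nt
        lengths = np.unique(np.linspace(lo, hi, n + 1).round().astype(int))
        if len(lengths) < n + 1:  # rounding collisions at tight spacing
            lengths = np.arange(lo, lo + 4 * (n + 1), 4)[: n + 1]
        spike_length = int(lengths[len(lengths) // 2])
        gene_lengths = [int(x) for x in lengths if x != spike_length]

        conc = 10 ** rng.uniform(
            math.log10(spec.conc_range_m[0]), math.log10(spec.conc_range_m[1]), n
        )
        stocks = 10 ** rng.uniform(
            math.log10(spec.primer_stock_range_um[0]),
            math.log10(spec.primer_stock_range_um[1]),
            n,
        )
        n_up = int(round(spec.frac_up * n))
        n_down = int(round(spec.frac_down * n))
        reg_pool = (
            [Regulation.UP] * n_up
            + [Regulation.DOWN] * n_down
            + [Regulation.CONSTANT] * (n - n_up - n_down)
        )
        rng.shuffle(reg_pool)  # type: ignore[arg-type]

        if reaction_order == 1.0:
            conc_values = conc
            kprime_values = np.array(
                [
                    spec.hybridization_rate * final_primer_concentration(float(s))
                    for s in stocks
                ]
            )
            gain = 1e9
        else:
            # low-conversion regime in relative units (see docstring)
            conc_values = conc / conc.max()
            stock_ratio = spec.primer_stock_range_um[1] / spec.primer_stock_range_um[0]
            exponent = math.log(kt_spread) / math.log(stock_ratio)
            kt = kt_max * (stocks / stocks.max()) ** exponent
            kprime_values = kt / spec.rt_time_s
            gain = 1e-3

        entries = []
        initial_conc: dict[str, float] = {}
        kprime: dict[str, float] = {}
        regulation: dict[str, Regulation] = {}
        fold: dict[str, float] = {}
        for i in range(n):
            gene_id = f"g{i + 1:02d}"
            entries.append(
                PanelEntry(
                    gene_id=gene_id,
                    expected_length_nt=gene_lengths[i],
                    is_spike_in=False,
                    rt_primer_conc_um=float(stocks[i]),
                )
            )
            initial_conc[gene_id] = float(conc_values[i])
            kprime[gene_id] = float(kprime_values[i])
            regulation[gene_id] = reg_pool[i]
            fold[gene_id] = spec.fold_change if reg_pool[i] != Regulation.CONSTANT else 1.0
        entries.append(
            PanelEntry(
                gene_id=SPIKE_GENE_ID,
                expected_length_nt=spike_length,
                is_spike_in=True,
                rt_primer_conc_um=0.05,
            )
        )
        return cls(
            panel=GenePanel(entries),
            initial_conc=initial_conc,
            kprime=kprime,
            regulation=regulation,
            fold_change=fold,
            reaction_order=reaction_order,
            rt_time_s=spec.rt_time_s,
            gain=gain,
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.initial_conc)

    def expected_area(self, gene_id: str, conc: float) -> float:
        """Noise-free peak area for a gene at a given transcript concentration."""
        amount = amplified_cdna(
            conc, self.kprime[gene_id], self.rt_time_s, self.reaction_order, self.pcr
        )
        return self.gain * amount

    def expected_npa(self, gene_id: str, conc: float) -> float:
        return self.expected_area(gene_id, conc) / self.spike_area

    def simulate_run(
        self,
        run_id: str,
        sample_id: str,
        conc_scale: float | dict[str, float],
        noise: NoiseSpec = NoiseSpec(),
        rng: Optional[np.random.Generator] = None,
    ) -> SeparationRun:
        """One separation run of a sample whose transcripts are at
        ``initial_conc * conc_scale`` (scalar dilution or per-gene map)."""
        rng = rng if rng is not None else np.random.default_rng(0)
        run_scale = float(rng.uniform(*noise.run_scale_range))

        def noisy_area(area: float) -> float:
            if noise.area_sigma > 0:
                area *= math.exp(rng.normal(0.0, noise.area_sigma))
            return area * run_scale

        def noisy_length(length: float) -> float:
            if noise.length_jitter_nt > 0:
                length += rng.normal(0.0, noise.length_jitter_nt)
            return length

        fragments: list[FragmentRecord] = []
        index = 1
        for entry in self.panel:
            if entry.is_spike_in:
                area = noisy_area(self.spike_area)
            else:
                scale = (
                    conc_scale
                    if isinstance(conc_scale, (int, float))
                    else conc_scale.get(entry.gene_id, 0.0)
                )
                area = noisy_area(
                    self.expected_area(entry.gene_id, self.initial_conc[entry.gene_id] * scale)
                )
            if area < self.detection_area:
                continue  # peak not called by the instrument
            fragments.append(
                FragmentRecord(
                    fragment_index=index,
                    length_nt=noisy_length(float(entry.expected_length_nt)),
                    peak_height=area / 10.0,  # crude but monotone height proxy
                    peak_area=area,
                )
            )
            index += 1
        return SeparationRun(run_id=run_id, sample_id=sample_id, fragments=fragments)


@dataclass
class DilutionDataset:
    """A simulated calibration experiment plus its ground truth."""

    assay: SyntheticAssay
    runs: list[SeparationRun]
    samples: pd.DataFrame  # sample_id, run_id, total_rna_ng, replicate
    ground_truth: pd.DataFrame  # gene_id, initial_conc, kprime, regulation

    def npa_table(self) -> pd.DataFrame:
        """NPA rows for all runs merged with total-RNA metadata."""
        frames = []
        meta = self.samples.set_index("run_id")
        for run in self.runs:
            npa = normalize_run(run, self.assay.panel)
            npa["total_rna_ng"] = meta.loc[run.run_id, "total_rna_ng"]
            frames.append(npa)
        return pd.concat(frames, ignore_index=True)


def generate_dilution_series(
    assay: SyntheticAssay,
    dilutions_ng: Sequence[float] = DEFAULT_DILUTIONS_NG,
    replicates: int = 2,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> DilutionDataset:
    """Simulate a two-fold dilution calibration experiment.

    Each concentration is measured ``replicates`` times with independent
    runs (default twice).  Transcript concentrations scale with total RNA
    input relative to the assay's 100 ng reference.
    """
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    runs: list[SeparationRun] = []
    rows = []
    for ng in dilutions_ng:
        if ng <= 0:
            raise InvalidParameterError("dilution amounts must be > 0 ng")
        for rep in range(1, replicates + 1):
            sample_id = f"std_{ng:g}ng"
            run_id = f"{sample_id}_r{rep}"
            runs.append(
                assay.simulate_run(
                    run_id, sample_id, ng / assay.reference_input_ng, noise, rng
                )
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "run_id": run_id,
                    "total_rna_ng": float(ng),
                    "replicate": rep,
                }
            )
    truth = pd.DataFrame(
        {
            "gene_id": assay.gene_ids,
            "initial_conc_m": [assay.initial_conc[g] for g in assay.gene_ids],
            "kprime_per_s": [assay.kprime[g] for g in assay.gene_ids],
            "regulation": [assay.regulation[g].value for g in assay.gene_ids],
            "reaction_order": assay.reaction_order,
        }
    )
    return DilutionDataset(
        assay=assay,
        runs=runs,
        samples=pd.DataFrame(rows),
        ground_truth=truth,
    )


def generate_mixing_series(
    assay: SyntheticAssay,
    ratios: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate mixing two RNA pools at varying ratios (co-amplification QC).

    Pool A holds each gene at its base concentration; in pool B up-regulated
    genes are ``fold_change`` higher and down-regulated genes lower, the
    spike-in constant.  With first-order RT kinetics the expected NPA of a
    mix is exactly linear in the fraction of pool A.  Returns (npa_table
    with columns ratio/gene_id/npa, ground_truth with per-pool NPAs).
    """
    ratios = [float(r) for r in ratios]
    if any(r < 0 or r > 1 for r in ratios):
        raise InvalidParameterError("ratios must lie in [0, 1]")
    if len(set(ratios)) < 3:
        raise InvalidParameterError("need >= 3 distinct mixing ratios")
    rng = np.random.default_rng(seed)
    pool_b_scale = {
        g: (
            assay.fold_change[g]
            if assay.regulation[g] == Regulation.UP
            else 1.0 / assay.fold_change[g]
            if assay.regulation[g] == Regulation.DOWN
            else 1.0
        )
        for g in assay.gene_ids
    }
    frames = []
    for i, r in enumerate(ratios):
        scale = {g: r + (1.0 - r) * pool_b_scale[g] for g in assay.gene_ids}
        run = assay.simulate_run(f"mix_{i}", f"mix_{r:g}", scale, noise, rng)
        npa = normalize_run(run, assay.panel)
        npa["ratio"] = r
        frames.append(npa)
    table = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "gene_id": assay.gene_ids,
            "npa_pool_a": [
                assay.expected_npa(g, assay.initial_conc[g]) for g in assay.gene_ids
            ],
            "npa_pool_b": [
                assay.expected_npa(g, assay.initial_conc[g] * pool_b_scale[g])
                for g in assay.gene_ids
            ],
            "regulation": [assay.regulation[g].value for g in assay.gene_ids],
        }
    )
    return table, truth


def generate_replicate_timeseries(
    assay: SyntheticAssay,
    n_cells: int = 26,
    n_timepoints: int = 5,
    replicate_sigma_log2: float = 0.7,
    detection_limit_rel: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired technical-replicate measurements over single-cell time series.

    Each cell contributes one expression trajectory per gene (regulated
    genes ramp up or down to their fold change across the time points, with
    lognormal cell-to-cell variability); every sample is then "measured"
    twice by drawing two independent lognormal replicates around the true
    value (``replicate_sigma_log2`` in log2 units).  Values below
    ``detection_limit_rel`` are flagged below-limit.  Yields
    ``n_cells * n_timepoints * n_genes`` pair rows before exclusions.
    """
    if n_cells < 1 or n_timepoints < 1:
        raise InvalidParameterError("n_cells and n_timepoints must be >= 1")
    if replicate_sigma_log2 < 0:
        raise InvalidParameterError("replicate_sigma_log2 must be >= 0")
    rng = np.random.default_rng(seed)
    base = {g: 10 ** rng.uniform(-1.0, 1.0) for g in assay.gene_ids}
    rows = []
    tgrid = np.linspace(0.0, 1.0, n_timepoints)
    for cell in range(1, n_cells + 1):
        cell_scale = {
            g: math.exp(rng.normal(0.0, 0.3)) for g in assay.gene_ids
        }  # cell-to-cell variability
        for ti, t in enumerate(tgrid):
            for g in assay.gene_ids:
                reg = assay.regulation[g]
                fc = assay.fold_change[g]
                if reg == Regulation.UP:
                    true = base[g] * cell_scale[g] * fc**t
                elif reg == Regulation.DOWN:
                    true = base[g] * cell_scale[g] * fc**-t
                else:
                    true = base[g] * cell_scale[g]
                v1 = true * 2 ** rng.normal(0.0, replicate_sigma_log2)
                v2 = true * 2 ** rng.normal(0.0, replicate_sigma_log2)
                rows.append(
                    {
                        "sample_id": f"P{cell}_t{ti}",
                        "gene_id": g,
                        "timepoint": ti,
                        "true_value": true,
                        "value_1": v1,
                        "value_2": v2,
                        "below_limit_1": v1 < detection_limit_rel,
                        "below_limit_2": v2 < detection_limit_rel,
                    }
                )
    return pd.DataFrame(rows)


def write_dataset(dataset: DilutionDataset, out_dir: str | Path) -> Path:
    """Write a dilution dataset as flat files: fragment tables, panel,
    sample manifest and ground truth.  Returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_panel(dataset.assay.panel, out / "panel.tsv")
    for run in dataset.runs:
        write_fragment_table(run, out / f"{run.run_id}.tsv")
    manifest = dataset.samples.copy()
    manifest["path"] = [f"{rid}.tsv" for rid in manifest["run_id"]]
    manifest["role"] = "standard"
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    dataset.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return out
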