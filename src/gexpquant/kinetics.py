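"""Forward kinetic model of multiplex reverse transcription and PCR.

The model treats gene-specific priming of reverse transcription as the
rate-limiting step.  Primer hybridization to its template RNA is a
second-order reaction, but because every attenuated reverse primer is in
large excess over its transcript, the primer concentration is effectively
constant and the rate law collapses to a pseudo first-order law with an
empirical reaction order ``n``::

    -d[RNA_i]/dt = k'_{i,j} * [RNA_i]**n,     k'_{i,j} = k_{i,j} * [Primer_{i,j}]

For ``n = 1`` the template decays exponentially; for ``n != 1`` the
closed-form solution of the separated integral is

    [RNA_i] = (k' * t * (n - 1) + [RNA_i]_0**(1 - n)) ** (1 / (1 - n))

First-strand cDNA is the consumed template, ``[RNA_i]_0 - [RNA_i]``, and
PCR multiplies it by an overall amplification factor ``alpha``.  With ``c``
cycles and per-cycle efficiency ``e``, ``alpha = (1 + e)**(c - 1)``: the
first cycle only synthesizes the second strand, bounding amplification by
``2**(c-1)`` at perfect efficiency.

A consequence used throughout calibration: plotting amplified cDNA against
total-RNA input double-logarithmically gives, for a shared ``n``, a family
of parallel lines — slope exactly 1 when ``n = 1`` and a common slope
below 1 when ``n < 1`` — regardless of per-gene rate constants.

Units: concentrations in molar, time in any unit consistent with the rate
constants (``k' * t`` enters only as a dimensionless product).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, InvalidParameterError

__all__ = [
    "Regulation",
    "TranscriptSpecies",
    "RTPrimerSpec",
    "RTReactionSpec",
    "PCRSpec",
    "CellEstimateInputs",
    "pseudo_rate",
    "remaining_rna",
    "first_strand_cdna",
    "amplified_cdna",
    "DilutionPrediction",
    "predict_dilution_curve",
    "fit_loglog_slopes",
    "estimate_average_transcript",
    "final_primer_concentration",
    "AVOGADRO",
]

AVOGADRO = 6.02214076e23  # mol^-1


class Regulation(str, enum.Enum):
    """Regulation class of a transcript (simulation metadata only)."""

    UP = "up"
    DOWN = "down"
    CONSTANT = "constant"


@dataclass(frozen=True)
class TranscriptSpecies:
    """A gene's mRNA species with its initial molar concentration."""

    gene_id: str
    initial_conc: float  # M
    regulation: Regulation = Regulation.CONSTANT

    def __post_init__(self) -> None:
        if self.initial_conc < 0:
            raise InvalidParameterError(
                f"{self.gene_id}: initial_conc must be >= 0, got {self.initial_conc}"
            )


@dataclass(frozen=True)
class RTPrimerSpec:
    """Gene-specific reverse-transcription primer: concentration and rate constant.

    ``primer_conc`` is the concentration in the RT reaction (M) and
    ``hybridization_rate`` the second-order rate constant for primer/template
    hybridization (M^-1 per unit time).
    """

    gene_id: str
    primer_conc: float
    hybridization_rate: float

    def __post_init__(self) -> None:
        if self.primer_conc <= 0:
            raise InvalidParameterError(
                f"{self.gene_id}: primer_conc must be > 0, got {self.primer_conc}"
            )
        if self.hybridization_rate <= 0:
            raise InvalidParameterError(
                f"{self.gene_id}: hybridization_rate must be > 0, "
                f"got {self.hybridization_rate}"
            )


@dataclass(frozen=True)
class RTReactionSpec:
    """Reverse-transcription reaction: primer pool, reaction order and time."""

    primers: tuple[RTPrimerSpec, ...]
    reaction_order: float = 1.0
    rt_time: float = 3600.0  # same time unit as 1/hybridization_rate
    volume: float = 10e-6  # litres

    def __post_init__(self) -> None:
        if self.reaction_order <= 0:
            raise InvalidParameterError(
                f"reaction_order must be > 0, got {self.reaction_order}"
            )
        if self.rt_time < 0:
            raise InvalidParameterError(f"rt_time must be >= 0, got {self.rt_time}")
        if self.volume <= 0:
            raise InvalidParameterError(f"volume must be > 0, got {self.volume}")
        seen: set[str] = set()
        for p in self.primers:
            if p.gene_id in seen:
                raise InvalidParameterError(f"duplicate primer for gene {p.gene_id}")
            seen.add(p.gene_id)
        object.__setattr__(self, "primers", tuple(self.primers))

    def primer_for(self, gene_id: str) -> RTPrimerSpec:
        for p in self.primers:
            if p.gene_id == gene_id:
                return p
        raise InvalidParameterError(f"no RT primer defined for gene {gene_id}")


@dataclass(frozen=True)
class PCRSpec:
    """PCR program: cycle count and per-cycle amplification efficiency.

    Efficiency 1.0 means perfect doubling each cycle after the second-strand
    synthesis cycle, giving the theoretical bound alpha = 2**(cycles-1).
    """

    cycles: int = 35
    per_cycle_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise InvalidParameterError(f"cycles must be >= 1, got {self.cycles}")
        if not 0.0 < self.per_cycle_efficiency <= 1.0:
            raise InvalidParameterError(
                "per_cycle_efficiency must be in (0, 1], "
                f"got {self.per_cycle_efficiency}"
            )

    @property
    def amplification(self) -> float:
        """Overall amplification alpha = (1 + efficiency)**(cycles - 1)."""
        return (1.0 + self.per_cycle_efficiency) ** (self.cycles - 1)


@dataclass(frozen=True)
class CellEstimateInputs:
    """Back-of-the-envelope inputs for the average-transcript estimate.

    Defaults describe a typical RT reaction on total RNA from a starving
    *Physarum polycephalum* plasmodium: 20 ng total RNA of which at most 2%
    is mRNA, ~17,000 expressed genes, ~1000 nt mean mature-mRNA length, in
    a 10 uL reaction.  ``nt_molar_mass`` defaults to 340 g/mol per
    nucleotide of single-stranded RNA.
    """

    total_rna_mass_ng: float = 20.0
    mrna_fraction: float = 0.02
    n_genes: int = 17_000
    mean_mrna_length_nt: float = 1000.0
    reaction_volume_l: float = 10e-6
    nt_molar_mass: float = 340.0

    def __post_init__(self) -> None:
        for name in (
            "total_rna_mass_ng",
            "mrna_fraction",
            "n_genes",
            "mean_mrna_length_nt",
            "reaction_volume_l",
            "nt_molar_mass",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.mrna_fraction > 1:
            raise InvalidParameterError("mrna_fraction must be <= 1")

    @property
    def mrna_mass_ng(self) -> float:
        """Total mRNA mass in the reaction (ng)."""
        return self.total_rna_mass_ng * self.mrna_fraction


def pseudo_rate(primer: RTPrimerSpec) -> float:
    """Pseudo first-order rate constant k' = k * [Primer] (per unit time)."""
    return primer.hybridization_rate * primer.primer_conc


def remaining_rna(rna0: float, kprime: float, t: float, n: float = 1.0) -> float:
    """Template RNA concentration remaining after RT time ``t``.

    ``n = 1``: exponential decay ``rna0 * exp(-k' t)``.  ``n != 1``: the
    closed-form power-law solution, clamped to ``[0, rna0]`` — for
    ``n < 1`` the template is exhausted in finite time and the result is 0
    from then on rather than a complex number.
    """
    if rna0 < 0:
        raise InvalidParameterError(f"rna0 must be >= 0, got {rna0}")
    if kprime <= 0:
        raise InvalidParameterError(f"kprime must be > 0, got {kprime}")
    if t < 0:
        raise InvalidParameterError(f"t must be >= 0, got {t}")
    if n <= 0:
        raise InvalidParameterError(f"reaction order must be > 0, got {n}")
    if t == 0 or rna0 == 0:
        return rna0
    if n == 1:
        return rna0 * math.exp(-kprime * t)
    base = kprime * t * (n - 1.0) + rna0 ** (1.0 - n)
    if base <= 0.0:
        # n < 1: template exhausted before t
        return 0.0
    value = base ** (1.0 / (1.0 - n))
    return min(max(value, 0.0), rna0)


def first_strand_cdna(rna0: float, kprime: float, t: float, n: float = 1.0) -> float:
    """First-strand cDNA synthesized during RT: consumed template rna0 - [RNA]."""
    return rna0 - remaining_rna(rna0, kprime, t, n)


def amplified_cdna(
    rna0: float, kprime: float, t: float, n: float = 1.0, pcr: PCRSpec = PCRSpec()
) -> float:
    """Amplified cDNA after PCR: alpha * first-strand amount.

    For ``n = 1`` the result is exactly proportional to ``rna0``, which is
    what makes log-log calibration lines of slope 1 the first-order
    prediction.
    """
    return pcr.amplification * first_strand_cdna(rna0, kprime, t, n)


class DilutionPrediction(NamedTuple):
    """Predicted dilution response: long table plus per-gene log-log slopes."""

    table: pd.DataFrame  # gene_id, dilution_factor, log10_total_rna, log10_amount
    slopes: "pd.Series[float]"  # gene_id -> fitted log10-log10 slope


def predict_dilution_curve(
    species: Sequence[TranscriptSpecies],
    rt: RTReactionSpec,
    pcr: PCRSpec,
    dilution_factors: Sequence[float],
) -> DilutionPrediction:
    """Predict amplified cDNA across a total-RNA dilution series.

    Every transcript is scaled by the same dilution factor (gene-specific
    mRNA concentration is proportional to total RNA input).  Returns the
    double-log table and the per-gene fitted slope.  With a shared reaction
    order the slopes are equal across genes (parallel lines); they equal 1
    exactly when ``n = 1``.
    """
    factors = [float(d) for d in dilution_factors]
    if any(d <= 0 for d in factors):
        raise InvalidParameterError("dilution factors must be > 0")
    if len(set(factors)) < 2:
        raise DegenerateFitError(
            "at least 2 distinct dilution factors are required to fit a slope"
        )
    rows = []
    for sp in species:
        kp = pseudo_rate(rt.primer_for(sp.gene_id))
        for d in factors:
            amount = amplified_cdna(
                sp.initial_conc * d, kp, rt.rt_time, rt.reaction_order, pcr
            )
            rows.append(
                {
                    "gene_id": sp.gene_id,
                    "dilution_factor": d,
                    "log10_total_rna": math.log10(d),
                    "log10_amount": math.log10(amount) if amount > 0 else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    return DilutionPrediction(table=table, slopes=fit_loglog_slopes(table))


def fit_loglog_slopes(table: pd.DataFrame) -> "pd.Series[float]":
    """Per-gene OLS slope of log10(amount) on log10(total RNA)."""
    slopes: dict[str, float] = {}
    for gene_id, sub in table.groupby("gene_id", sort=False):
        sub = sub.dropna(subset=["log10_amount"])
        if len(sub) < 2:
            raise DegenerateFitError(f"{gene_id}: need >= 2 points for a slope")
        slope, _ = np.polyfit(sub["log10_total_rna"], sub["log10_amount"], 1)
        slopes[str(gene_id)] = float(slope)
    return pd.Series(slopes, name="slope")


def estimate_average_transcript(
    inputs: CellEstimateInputs = CellEstimateInputs(),
) -> tuple[float, float]:
    """Average per-gene mRNA concentration (M) and molecule count per reaction.

    Divides the mRNA mass evenly over the expressed genes, converts via the
    mean transcript molar mass (length * per-nucleotide mass), and scales
    by the reaction volume.  With the defaults this reproduces the familiar
    orders of magnitude: ~6.9e-15 M and ~41,500 molecules per 10 uL.
    """
    mass_g = inputs.mrna_mass_ng * 1e-9
    per_gene_moles = (mass_g / inputs.n_genes) / (
        inputs.mean_mrna_length_nt * inputs.nt_molar_mass
    )
    conc = per_gene_moles / inputs.reaction_volume_l
    count = per_gene_moles * AVOGADRO
    return conc, count


def final_primer_concentration(
    stock_conc_um: float,
    pipetted_volume_ul: float = 1.0,
    reaction_volume_ul: float = 10.0,
) -> float:
    """Final molar primer concentration in the RT reaction.

    The attenuated reverse-primer plex (stock concentrations per primer) is
    diluted into the reaction: by default 1 uL of mix in a 10 uL reaction,
    so a 0.00025 uM stock yields 2.5e-11 M and a 0.5 uM stock 5e-8 M.
    """
    if stock_conc_um <= 0 or pipetted_volume_ul <= 0 or reaction_volume_ul <= 0:
        raise InvalidParameterError("volumes and concentrations must be > 0")
    if pipetted_volume_ul > reaction_volume_ul:
        raise InvalidParameterError("pipetted volume cannot exceed reaction volume")
    return stock_conc_um * 1e-6 * pipetted_volume_ul / reaction_volume_ul
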