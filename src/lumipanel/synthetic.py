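"""Seeded simulator for assay MFI matrices and dilution series.

Signal model: reactive cells draw log-normal MFIs (decade-spanning positives);
non-reactive cells draw from a zero-truncated normal background (tight
negatives).  Which cells are reactive follows from the simulated truth via the
antigen-carriage relation on glycoprotein beads; HLA-bead reactivity is a
per-donor Bernoulli draw, the minimal mechanism producing partial HLA
patterns without modelling donor HLA types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lumipanel.panel_model import (
    BeadPanel,
    DonorPanel,
    HLA_CAPTURE,
    HPA_CAPTURE,
    Specificity,
    carries,
)
from lumipanel.reactivity import MfiMatrix
from lumipanel.titration import DilutionSeries


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Everything a reproducible assay simulation needs.

    ``truth`` maps sample_id -> the specificity set actually present in that
    serum.  Signal/background defaults are calibrated to the clinical fixture:
    positives around 10^3 MFI with 0.3 log10-decades of spread, background
    around 60 +/- 25 truncated at zero.
    """

    donor_panel: DonorPanel
    bead_panel: BeadPanel
    truth: Mapping[str, frozenset[Specificity]]
    n_negative_controls: int = 8
    signal_log10_mean: float = 3.0
    signal_log10_sd: float = 0.3
    background_mean: float = 60.0
    background_sd: float = 25.0
    hla_reactive_fraction: float = 0.75
    dilution_rho: float = 0.65
    dilution_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution_rho < 1.0):
            raise SimulationError(f"dilution_rho must be in (0,1): {self.dilution_rho}")
        if self.signal_log10_sd < 0 or self.background_sd <= 0:
            raise SimulationError("signal/background SDs must be positive")
        if not (0.0 <= self.hla_reactive_fraction <= 1.0):
            raise SimulationError(
                f"hla_reactive_fraction outside [0,1]: {self.hla_reactive_fraction}"
            )
        self._validate_truth()

    def _validate_truth(self) -> None:
        active_systems = {
            s for b in self.bead_panel.active_hpa for s in b.systems
        }
        has_hla = self.bead_panel.hla_bead is not None
        for sample_id, specs in self.truth.items():
            for spec in specs:
                if spec.kind == "anti-HLA":
                    if not has_hla:
                        raise SimulationError(
                            f"truth for {sample_id} includes anti-HLA but no "
                            "active HLA bead exists"
                        )
                elif spec.system not in active_systems:
                    raise SimulationError(
                        f"truth for {sample_id} references system {spec.system} "
                        "carried by no active bead (disabled or undefined)"
                    )


def _expected_reactive(
    config: SimulationConfig,
    specs: frozenset[Specificity],
    donor_id: str,
    bead,
    rng: np.random.Generator,
) -> bool:
    if bead.role == HLA_CAPTURE:
        if any(s.kind == "anti-HLA" for s in specs):
            return bool(rng.random() < config.hla_reactive_fraction)
        return False
    donor = config.donor_panel.donor(donor_id)
    return any(
        s.kind == "anti-HPA"
        and s.system in bead.systems
        and carries(donor, s.system, s.allele)
        for s in specs
    )


def _draw_background(config: SimulationConfig, rng: np.random.Generator) -> float:
    a = (0.0 - config.background_mean) / config.background_sd
    return float(
        stats.truncnorm.rvs(
            a, np.inf,
            loc=config.background_mean,
            scale=config.background_sd,
            random_state=rng,
        )
    )


def _draw_signal(config: SimulationConfig, rng: np.random.Generator) -> float:
    return float(
        10.0 ** rng.normal(config.signal_log10_mean, config.signal_log10_sd)
    )


def simulate_assay(config: SimulationConfig) -> tuple[MfiMatrix, pd.DataFrame]:
    """Simulate MFIs for every (sample, donor, active bead) cell plus controls.

    Returns the MFI matrix (test samples and ``NC1..NCn`` negative controls,
    with a ``role`` column) and a truth table ``sample_id, truth`` with the
    simulated call strings.  Bit-identical for identical configs/seeds.
    """
    rng = np.random.default_rng(config.seed)
    beads = [
        b for b in config.bead_panel.active if b.role in (HPA_CAPTURE, HLA_CAPTURE)
    ]
    records: list[tuple[str, str, str, float, str]] = []
    for sample_id in config.truth:
        specs = config.truth[sample_id]
        for bead in beads:
            for donor_id in config.donor_panel.donor_ids:
                if _expected_reactive(config, specs, donor_id, bead, rng):
                    value = _draw_signal(config, rng)
                else:
                    value = _draw_background(config, rng)
                records.append((sample_id, donor_id, bead.bead_id, value, "test"))
    for i in range(config.n_negative_controls):
        sample_id = f"NC{i + 1}"
        for bead in beads:
            for donor_id in config.donor_panel.donor_ids:
                records.append(
                    (
                        sample_id,
                        donor_id,
                        bead.bead_id,
                        _draw_background(config, rng),
                        "negative_control",
                    )
                )
    frame = pd.DataFrame(
        records, columns=["sample_id", "donor_id", "bead_id", "mfi", "role"]
    )
    from lumipanel.panel_model import format_call

    truth_table = pd.DataFrame(
        {
            "sample_id": list(config.truth),
            "truth": [format_call(config.truth[s]) for s in config.truth],
        }
    )
    return MfiMatrix(frame), truth_table


def detectable_specificities(
    donor_panel: DonorPanel, bead_panel: BeadPanel
) -> tuple[Specificity, ...]:
    """Anti-HPA specificities the pipeline can recover as a lone truth.

    A specificity is detectable when at least one panel donor carries the
    antigen *and* the noise-free reactivity pattern it produces deconvolves
    back to exactly that specificity at rank 1 (priors included).  Simulated
    truths drawn from this set make exact-recovery rates meaningful.
    """
    from lumipanel.deconvolution import infer_bead

    out: list[Specificity] = []
    donor_ids = frozenset(donor_panel.donor_ids)
    for bead in bead_panel.active_hpa:
        from lumipanel.panel_model import candidate_specificities

        for spec in sorted(candidate_specificities(bead), key=Specificity.sort_key):
            reactive = donor_panel.carriers(spec.system, spec.allele)
            if not reactive:
                continue
            ranked = infer_bead(bead, reactive, donor_ids - reactive, donor_panel)
            if ranked and ranked[0].specificities == frozenset({spec}):
                out.append(spec)
    return tuple(out)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def expected_dilution_mfi(
    config: SimulationConfig, amplitude: float, factor: int
) -> float:
    """Noise-free decay: background + amplitude * rho^log2(factor)."""
    return config.background_mean + amplitude * config.dilution_rho ** math.log2(factor)


def analytic_titer(
    config: SimulationConfig,
    amplitude: float,
    factors: Sequence[int],
    cutoff: float,
) -> int:
    """Largest factor whose noise-free expected MFI crosses the cutoff.

    Closed-form companion of :func:`simulate_dilution` used to validate the
    endpoint-titer rule; 0 when even the first factor is below the cutoff.
    """
    positive = [
        f for f in factors if expected_dilution_mfi(config, amplitude, f) >= cutoff
    ]
    return max(positive) if positive else 0


def simulate_dilution(
    config: SimulationConfig,
    base_sample: str,
    bead_id: str,
    factors: Sequence[int],
    amplitude: float | None = None,
) -> DilutionSeries:
    """Simulate a two-fold dilution series for one sample on one bead.

    ``mfi(f) = background_mean + A * rho^log2(f) + noise``, strictly
    decreasing in expectation.  Factors must be powers of two (the assay's
    doubling-dilution scheme), strictly increasing.  ``amplitude`` defaults to
    a draw from the signal model.
    """
    factors = [int(f) for f in factors]
    bad = [f for f in factors if not _is_power_of_two(f)]
    if bad:
        raise SimulationError(
            f"dilution factors must be powers of two (doubling scheme), got {bad}"
        )
    if any(b <= a for a, b in zip(factors, factors[1:])):
        raise SimulationError(f"dilution factors must be strictly increasing: {factors}")
    rng = np.random.default_rng(config.seed)
    if amplitude is None:
        amplitude = _draw_signal(config, rng)
    if amplitude <= 0:
        raise SimulationError(f"amplitude must be positive, got {amplitude}")
    points = []
    for f in factors:
        value = expected_dilution_mfi(config, amplitude, f)
        if config.dilution_noise_sd > 0:
            value += rng.normal(0.0, config.dilution_noise_sd)
        points.append((f, max(value, 0.0)))
    return DilutionSeries(sample_id=base_sample, bead_id=bead_id, points=tuple(points))
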