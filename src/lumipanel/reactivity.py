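"""Cutoff estimation from negative controls and binary reactivity calling.

The positivity rule is the assay's: per-bead cutoff = negative-control mean
MFI + 3 standard deviations, and a measurement is reactive iff MFI >= cutoff
(inclusive).  Values just above the cutoff (within ``grey_factor`` x cutoff)
are reactive but flagged *borderline*; the deconvolution layer treats
borderline-only reactivity as a warning rather than evidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from lumipanel.panel_model import BeadPanel, DonorPanel

logger = logging.getLogger(__name__)

DEFAULT_GREY_FACTOR = 1.25

#: sample roles recognized in MFI manifests
ROLES = ("test", "negative_control", "dilution", "positive_control")


class MfiError(ValueError):
    """Invalid MFI data."""


@dataclass(frozen=True)
class MfiMatrix:
    """Long-format (sample, donor, bead) -> MFI table.

    ``frame`` columns: ``sample_id, donor_id, bead_id, mfi`` and optional
    ``role``.  MFIs are arbitrary fluorescence units, >= 0.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "donor_id", "bead_id", "mfi"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise MfiError(f"MFI table missing columns {missing}")
        df = self.frame.copy()
        df["mfi"] = df["mfi"].astype(float)
        if not np.isfinite(df["mfi"]).all():
            raise MfiError("non-finite MFI value")
        if (df["mfi"] < 0).any():
            bad = df.loc[df["mfi"] < 0].iloc[0]
            raise MfiError(
                f"negative MFI {bad['mfi']} at ({bad['sample_id']}, "
                f"{bad['donor_id']}, {bad['bead_id']}) — corrupt input"
            )
        keys = df[["sample_id", "donor_id", "bead_id"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise MfiError(
                f"duplicate (sample, donor, bead) triple: "
                f"({dup['sample_id']}, {dup['donor_id']}, {dup['bead_id']})"
            )
        if "role" in df.columns:
            bad_roles = set(df["role"].dropna()) - set(ROLES)
            if bad_roles:
                raise MfiError(f"unknown sample roles {sorted(bad_roles)}")
        else:
            df["role"] = "test"
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], roles: Mapping[str, str] | None = None
    ) -> "MfiMatrix":
        """Build from ``(sample_id, donor_id, bead_id, mfi)`` tuples."""
        df = pd.DataFrame(
            list(records), columns=["sample_id", "donor_id", "bead_id", "mfi"]
        )
        if roles:
            df["role"] = df["sample_id"].map(roles).fillna("test")
        return cls(df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["sample_id"]))

    @property
    def bead_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["bead_id"]))

    @property
    def donor_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["donor_id"]))

    def with_role(self, role: str) -> "MfiMatrix":
        sub = self.frame[self.frame["role"] == role]
        if sub.empty:
            raise MfiError(f"no samples with role {role!r}")
        return MfiMatrix(sub)

    def restrict_samples(self, sample_ids: Iterable[str]) -> "MfiMatrix":
        wanted = set(sample_ids)
        return MfiMatrix(self.frame[self.frame["sample_id"].isin(wanted)])

    def validate_against(
        self, donor_panel: DonorPanel, bead_panel: BeadPanel
    ) -> None:
        unknown_donors = set(self.frame["donor_id"]) - set(donor_panel.donor_ids)
        if unknown_donors:
            raise MfiError(f"MFI table references unknown donors {sorted(unknown_donors)}")
        known_beads = {b.bead_id for b in bead_panel}
        unknown_beads = set(self.frame["bead_id"]) - known_beads
        if unknown_beads:
            raise MfiError(f"MFI table references unknown beads {sorted(unknown_beads)}")


@dataclass(frozen=True)
class BeadCutoff:
    """Positivity threshold for one bead (optionally one bead x donor).

    Either derived from negative controls (mean + 3 SD, ``neg_mean``/``neg_sd``
    populated) or supplied directly (both ``None``).
    """

    bead_id: str
    cutoff: float
    neg_mean: float | None = None
    neg_sd: float | None = None
    n_controls: int | None = None
    donor_id: str | None = None

    def __post_init__(self) -> None:
        if self.cutoff < 0 or not math.isfinite(self.cutoff):
            raise MfiError(f"invalid cutoff {self.cutoff} for bead {self.bead_id}")
        if self.neg_mean is not None and self.neg_sd is not None:
            expected = self.neg_mean + 3.0 * self.neg_sd
            if not math.isclose(self.cutoff, expected, rel_tol=0, abs_tol=1e-9):
                raise MfiError(
                    f"bead {self.bead_id}: cutoff {self.cutoff} != "
                    f"neg_mean + 3*neg_sd = {expected}"
                )


@dataclass(frozen=True)
class CutoffSet:
    """Per-bead (or per bead x donor) cutoffs."""

    cutoffs: tuple[BeadCutoff, ...]

    def __post_init__(self) -> None:
        keys = [(c.bead_id, c.donor_id) for c in self.cutoffs]
        if len(set(keys)) != len(keys):
            raise MfiError(f"duplicate cutoff keys: {keys}")
        object.__setattr__(self, "cutoffs", tuple(self.cutoffs))

    def __iter__(self):
        return iter(self.cutoffs)

    def cutoff_for(self, bead_id: str, donor_id: str | None = None) -> float:
        by_key = {(c.bead_id, c.donor_id): c for c in self.cutoffs}
        hit = by_key.get((bead_id, donor_id)) or by_key.get((bead_id, None))
        if hit is None:
            raise MfiError(f"no cutoff for bead {bead_id!r}")
        return hit.cutoff

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "CutoffSet":
        """Directly supplied cutoffs, bead_id -> threshold."""
        return cls(tuple(BeadCutoff(bead_id=b, cutoff=v) for b, v in mapping.items()))


def compute_cutoffs(
    neg_mfi: MfiMatrix,
    beads: Iterable[str] | None = None,
    ddof: int = 1,
    per_donor: bool = False,
) -> CutoffSet:
    """Per-bead cutoff = mean + 3 x SD of the negative-control MFIs.

    Parameters
    ----------
    neg_mfi:
        MFI matrix restricted to negative-control samples (controls are pooled
        across panel donors unless ``per_donor``).
    beads:
        Beads that must receive a cutoff (default: all beads present).
    ddof:
        1 for the sample (n-1) standard deviation — the default, conservative
        choice — or 0 for the population SD.
    per_donor:
        Compute a separate cutoff per (bead, donor) instead of pooling.
    """
    df = neg_mfi.frame
    wanted = list(beads) if beads is not None else list(neg_mfi.bead_ids)
    group_cols = ["bead_id", "donor_id"] if per_donor else ["bead_id"]
    out: list[BeadCutoff] = []
    for key, grp in df.groupby(group_cols, sort=False):
        values = grp["mfi"].to_numpy()
        bead_id = key[0] if per_donor else (key if isinstance(key, str) else key[0])
        donor_id = key[1] if per_donor else None
        if len(values) < 2:
            raise MfiError(
                f"bead {bead_id!r}: {len(values)} negative-control value(s); "
                "need >= 2 to estimate the SD"
            )
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=ddof))
        out.append(
            BeadCutoff(
                bead_id=bead_id,
                donor_id=donor_id,
                cutoff=mean + 3.0 * sd,
                neg_mean=mean,
                neg_sd=sd,
                n_controls=len(values),
            )
        )
        logger.info(
            "cutoff bead=%s donor=%s n=%d mean=%.4g sd=%.4g cutoff=%.4g",
            bead_id, donor_id or "-", len(values), mean, sd, mean + 3.0 * sd,
        )
    covered = {c.bead_id for c in out}
    uncovered = [b for b in wanted if b not in covered]
    if uncovered:
        raise MfiError(f"no negative-control values for bead(s) {uncovered}")
    return CutoffSet(tuple(out))


@dataclass(frozen=True)
class BeadReactivity:
    """Reactive/non-reactive donor partition for one (sample, bead)."""

    sample_id: str
    bead_id: str
    reactive: frozenset[str]
    nonreactive: frozenset[str]
    borderline: frozenset[str]  # subset of reactive
    missing: frozenset[str]
    mfi: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reactive & self.nonreactive:
            raise MfiError("reactive and non-reactive donor sets overlap")
        if not self.borderline <= self.reactive:
            raise MfiError("borderline donors must be reactive")


@dataclass(frozen=True)
class ReactivityPattern:
    """All (sample, bead) partitions for a run."""

    cells: Mapping[tuple[str, str], BeadReactivity]

    def get(self, sample_id: str, bead_id: str) -> BeadReactivity | None:
        return self.cells.get((sample_id, bead_id))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s for s, _ in self.cells))

    def beads_for(self, sample_id: str) -> tuple[str, ...]:
        return tuple(b for s, b in self.cells if s == sample_id)


def call_reactivity(
    mfi: MfiMatrix,
    cutoffs: CutoffSet,
    donor_panel: DonorPanel | None = None,
    grey_factor: float = DEFAULT_GREY_FACTOR,
) -> ReactivityPattern:
    """Partition donors into reactive (MFI >= cutoff) and non-reactive per cell.

    Missing (sample, donor, bead) measurements — donors in ``donor_panel``
    with no value — are flagged and belong to neither set.  Reactive values
    below ``grey_factor * cutoff`` are additionally marked borderline.
    """
    if grey_factor < 1.0:
        raise MfiError(f"grey_factor must be >= 1, got {grey_factor}")
    panel_donors = donor_panel.donor_ids if donor_panel is not None else None
    cells: dict[tuple[str, str], BeadReactivity] = {}
    for (sample_id, bead_id), grp in mfi.frame.groupby(
        ["sample_id", "bead_id"], sort=False
    ):
        values = dict(zip(grp["donor_id"], grp["mfi"]))
        reactive, nonreactive, borderline = set(), set(), set()
        for donor_id, value in values.items():
            cutoff = cutoffs.cutoff_for(bead_id, donor_id)
            if value >= cutoff:
                reactive.add(donor_id)
                if value < grey_factor * cutoff:
                    borderline.add(donor_id)
                    logger.info(
                        "borderline sample=%s bead=%s donor=%s mfi=%.4g cutoff=%.4g",
                        sample_id, bead_id, donor_id, value, cutoff,
                    )
            else:
                nonreactive.add(donor_id)
        missing: set[str] = set()
        if panel_donors is not None:
            missing = set(panel_donors) - set(values)
            if missing:
                logger.warning(
                    "missing measurements sample=%s bead=%s donors=%s",
                    sample_id, bead_id, sorted(missing),
                )
        cells[(sample_id, bead_id)] = BeadReactivity(
            sample_id=sample_id,
            bead_id=bead_id,
            reactive=frozenset(reactive),
            nonreactive=frozenset(nonreactive),
            borderline=frozenset(borderline),
            missing=frozenset(missing),
            mfi=values,
        )
    return ReactivityPattern(cells)
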