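"""Specificity inference from reactivity patterns and donor genotypes.

For one glycoprotein bead, a set of antibody specificities *explains* the
observed donor partition when every reactive donor carries at least one of
the implicated antigens and no non-reactive donor carries any of them.  The
engine enumerates minimal consistent sets per bead, ranks them (smallest
first, then by a priori plausibility, then lexicographically), and unions the
top-ranked set of every bead into the sample's final call.  HLA reactivity is
called separately: any reactive donor on the HLA-capture bead makes the
sample anti-HLA positive (donor HLA types are unknown, so the per-donor
pattern is reported but not interpreted further).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence

from lumipanel.panel_model import (
    ANTI_HLA,
    Bead,
    BeadPanel,
    DonorPanel,
    HPA_CAPTURE,
    Specificity,
    UninformativeSpecificity,
    candidate_specificities,
    carries,
    format_call,
    uninformative_specificities,
)
from lumipanel.reactivity import ReactivityPattern

logger = logging.getLogger(__name__)

DEFAULT_MAX_SET_SIZE = 2
ORACLE_CANDIDATE_BOUND = 12


class InferenceError(ValueError):
    """Invalid inference request."""


#: Default a-priori plausibility weights in [0, 1].  They only break ties
#: between same-cardinality consistent sets; HPA-4 (and other systems whose
#: polymorphism is vanishingly rare in the studied population) gets a weight
#: low enough that an all-reactive GPIIb/IIIa pattern resolves to anti-HPA-1a.
DEFAULT_PRIOR_WEIGHTS: dict[str, float] = {
    "anti-HLA": 0.95,
    "anti-HPA-1a": 0.90,
    "anti-HPA-1b": 0.60,
    "anti-HPA-2a": 0.50,
    "anti-HPA-2b": 0.55,
    "anti-HPA-3a": 0.80,
    "anti-HPA-3b": 0.80,
    "anti-HPA-4a": 0.02,
    "anti-HPA-4b": 0.01,
    "anti-HPA-5a": 0.60,
    "anti-HPA-5b": 0.70,
    "anti-HPA-15a": 0.40,
    "anti-HPA-15b": 0.40,
}


@dataclass(frozen=True)
class PriorTable:
    """Specificity -> rarity weight in [0, 1]; higher = more plausible."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, w in self.weights.items():
            if not (0.0 <= w <= 1.0):
                raise InferenceError(f"prior weight for {label} outside [0,1]: {w}")

    @classmethod
    def default(cls) -> "PriorTable":
        return cls(dict(DEFAULT_PRIOR_WEIGHTS))

    def weight(self, spec: Specificity) -> float:
        try:
            return self.weights[spec.label]
        except KeyError:
            raise InferenceError(
                f"no prior weight for specificity {spec.label}"
            ) from None

    def score(self, specs: Iterable[Specificity]) -> float:
        """Joint plausibility of a set: product of member weights."""
        return math.prod(self.weight(s) for s in specs)

    def validate_coverage(self, bead_panel: BeadPanel) -> None:
        for bead in bead_panel.active:
            if bead.role == "positive_control":
                continue
            for spec in candidate_specificities(bead):
                self.weight(spec)


def consistent(
    spec_set: Iterable[Specificity],
    bead: Bead,
    reactive: Iterable[str],
    nonreactive: Iterable[str],
    panel: DonorPanel,
) -> bool:
    """True iff ``spec_set`` explains the partition exactly.

    (i) every reactive donor carries at least one implicated antigen, and
    (ii) no non-reactive donor carries any of them.
    """
    specs = list(spec_set)
    for donor_id in reactive:
        donor = panel.donor(donor_id)
        if not any(carries(donor, s.system, s.allele) for s in specs):
            return False
    for donor_id in nonreactive:
        donor = panel.donor(donor_id)
        if any(carries(donor, s.system, s.allele) for s in specs):
            return False
    return True


@dataclass(frozen=True)
class RankedSet:
    """One minimal consistent specificity set, with its rank among peers."""

    specificities: frozenset[Specificity]
    cardinality: int
    prior_score: float
    rank: int

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(s.label for s in self.specificities))


def _rank(sets: list[frozenset[Specificity]], priors: PriorTable) -> list[RankedSet]:
    def key(specs: frozenset[Specificity]):
        return (
            len(specs),
            -priors.score(specs),
            tuple(sorted(s.label for s in specs)),
        )

    ordered = sorted(sets, key=key)
    return [
        RankedSet(
            specificities=specs,
            cardinality=len(specs),
            prior_score=priors.score(specs),
            rank=i + 1,
        )
        for i, specs in enumerate(ordered)
    ]


def infer_bead(
    bead: Bead,
    reactive: frozenset[str],
    nonreactive: frozenset[str],
    panel: DonorPanel,
    priors: PriorTable | None = None,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
) -> list[RankedSet]:
    """Minimal consistent specificity sets for one glycoprotein bead.

    Enumerates candidate subsets in cardinality order up to ``max_set_size``,
    keeps the consistent ones, and drops any set with a consistent proper
    subset.  An empty reactive set yields an empty list (nothing to explain);
    a reactive set no candidate subset explains also yields an empty list —
    the caller flags it as unexplained.
    """
    if bead.role != HPA_CAPTURE:
        raise InferenceError(
            f"infer_bead applies to hpa_capture beads, not {bead.role!r} ({bead.bead_id})"
        )
    if max_set_size < 1:
        raise InferenceError(f"max_set_size must be >= 1, got {max_set_size}")
    if not reactive:
        return []
    priors = priors or PriorTable.default()
    candidates = sorted(candidate_specificities(bead), key=Specificity.sort_key)
    kept: list[frozenset[Specificity]] = []
    for size in range(1, min(max_set_size, len(candidates)) + 1):
        for combo in combinations(candidates, size):
            specs = frozenset(combo)
            if any(k < specs for k in kept):
                continue  # a consistent proper subset exists -> not minimal
            if consistent(specs, bead, reactive, nonreactive, panel):
                kept.append(specs)
    ranked = _rank(kept, priors)
    if len(ranked) > 1:
        logger.info(
            "tie-break bead=%s chosen=%s over=%s by=(cardinality,prior)",
            bead.bead_id,
            "+".join(ranked[0].labels),
            ["+".join(r.labels) for r in ranked[1:]],
        )
    return ranked


def oracle_infer(
    bead: Bead,
    reactive: frozenset[str],
    nonreactive: frozenset[str],
    panel: DonorPanel,
    priors: PriorTable | None = None,
) -> list[RankedSet]:
    """Brute-force reference: all subsets, minimality by pairwise subset test.

    Test oracle only — no size cap, no early pruning.  Bounded to beads with
    at most ``ORACLE_CANDIDATE_BOUND`` candidate specificities.
    """
    candidates = sorted(candidate_specificities(bead), key=Specificity.sort_key)
    if len(candidates) > ORACLE_CANDIDATE_BOUND:
        raise InferenceError(
            f"oracle bound exceeded: {len(candidates)} candidates > "
            f"{ORACLE_CANDIDATE_BOUND}"
        )
    if not reactive:
        return []
    all_subsets = [
        frozenset(c)
        for c in chain.from_iterable(
            combinations(candidates, r) for r in range(1, len(candidates) + 1)
        )
    ]
    consistent_sets = [
        s for s in all_subsets if consistent(s, bead, reactive, nonreactive, panel)
    ]
    minimal = [
        s
        for s in consistent_sets
        if not any(o < s for o in consistent_sets)
    ]
    return _rank(minimal, priors or PriorTable.default())


def infer_hla(pattern: ReactivityPattern, sample_id: str, hla_bead: Bead) -> bool:
    """Anti-HLA positive iff at least one donor is reactive on the HLA bead."""
    cell = pattern.get(sample_id, hla_bead.bead_id)
    if cell is None:
        return False
    return bool(cell.reactive)


@dataclass(frozen=True)
class Flag:
    """A machine-readable caveat attached to a call."""

    kind: str  # unexplained_reactivity | borderline_only | uninformative | missing_data
    bead_id: str | None = None
    detail: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"kind": self.kind, "bead_id": self.bead_id, "detail": list(self.detail)}


@dataclass(frozen=True)
class BeadInference:
    """Per-bead inference outcome inside a sample call."""

    bead_id: str
    reactive: frozenset[str]
    nonreactive: frozenset[str]
    borderline: frozenset[str]
    candidate_sets: tuple[RankedSet, ...]
    unexplained: bool
    borderline_only: bool


@dataclass(frozen=True)
class SpecificityCall:
    """Full interpretation of one sample."""

    sample_id: str
    beads: Mapping[str, BeadInference]
    hla_positive: bool
    final_call: frozenset[Specificity]
    flags: tuple[Flag, ...] = ()
    structural_limitations: tuple[UninformativeSpecificity, ...] = ()

    @property
    def negative(self) -> bool:
        return not self.final_call and not any(b.reactive for b in self.beads.values())

    @property
    def positive(self) -> bool:
        return any(b.reactive for b in self.beads.values())

    @property
    def call_string(self) -> str:
        return format_call(self.final_call)


def call_sample(
    sample_id: str,
    pattern: ReactivityPattern,
    donor_panel: DonorPanel,
    bead_panel: BeadPanel,
    priors: PriorTable | None = None,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
) -> SpecificityCall:
    """Interpret one sample across all active beads.

    The final call is the union of each glycoprotein bead's rank-1 minimal
    consistent set, plus anti-HLA when the HLA bead is reactive.  Beads whose
    reactivity is entirely borderline contribute flags, not calls.
    """
    priors = priors or PriorTable.default()
    beads: dict[str, BeadInference] = {}
    flags: list[Flag] = []
    final: set[Specificity] = set()

    for bead in bead_panel.active_hpa:
        cell = pattern.get(sample_id, bead.bead_id)
        if cell is None:
            flags.append(Flag("missing_data", bead.bead_id))
            continue
        if cell.missing:
            flags.append(Flag("missing_data", bead.bead_id, tuple(sorted(cell.missing))))
        ranked = tuple(
            infer_bead(
                bead, cell.reactive, cell.nonreactive, donor_panel, priors, max_set_size
            )
        )
        unexplained = bool(cell.reactive) and not ranked
        borderline_only = bool(cell.reactive) and cell.reactive == cell.borderline
        beads[bead.bead_id] = BeadInference(
            bead_id=bead.bead_id,
            reactive=cell.reactive,
            nonreactive=cell.nonreactive,
            borderline=cell.borderline,
            candidate_sets=ranked,
            unexplained=unexplained,
            borderline_only=borderline_only,
        )
        if unexplained:
            flags.append(
                Flag("unexplained_reactivity", bead.bead_id, tuple(sorted(cell.reactive)))
            )
        if borderline_only:
            flags.append(
                Flag("borderline_only", bead.bead_id, tuple(sorted(cell.borderline)))
            )
        if ranked and not borderline_only:
            final |= ranked[0].specificities

    hla_positive = False
    hla_bead = bead_panel.hla_bead
    if hla_bead is not None:
        cell = pattern.get(sample_id, hla_bead.bead_id)
        if cell is not None:
            hla_positive = infer_hla(pattern, sample_id, hla_bead)
            hla_borderline_only = bool(cell.reactive) and cell.reactive == cell.borderline
            beads[hla_bead.bead_id] = BeadInference(
                bead_id=hla_bead.bead_id,
                reactive=cell.reactive,
                nonreactive=cell.nonreactive,
                borderline=cell.borderline,
                candidate_sets=(
                    _rank([frozenset({ANTI_HLA})], priors)[0],
                ) if hla_positive else (),
                unexplained=False,
                borderline_only=hla_borderline_only,
            )
            if hla_positive and hla_borderline_only:
                flags.append(
                    Flag("borderline_only", hla_bead.bead_id, tuple(sorted(cell.borderline)))
                )
            elif hla_positive:
                final.add(ANTI_HLA)

    limitations = uninformative_specificities(donor_panel, bead_panel)
    call = SpecificityCall(
        sample_id=sample_id,
        beads=beads,
        hla_positive=hla_positive,
        final_call=frozenset(final),
        flags=tuple(flags),
        structural_limitations=limitations,
    )
    logger.info(
        "call sample=%s final=%s flags=%s",
        sample_id,
        call.call_string,
        [f.kind for f in flags] or "-",
    )
    return call


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between this engine's calls and a reference method."""

    n_compared: int
    n_agree: int
    discordant: tuple[tuple[str, str, str], ...]  # (sample, ours, reference)
    missing_reference: tuple[str, ...]

    @property
    def percent_agreement(self) -> float:
        if self.n_compared == 0:
            raise InferenceError("no overlapping samples between calls and reference")
        return 100.0 * self.n_agree / self.n_compared


def concordance(
    calls: Sequence[SpecificityCall],
    reference: Mapping[str, frozenset[Specificity]],
) -> ConcordanceReport:
    """Set-equality comparison of final calls against reference-method calls.

    Samples with no reference entry are listed and excluded from the
    denominator.
    """
    discordant: list[tuple[str, str, str]] = []
    missing: list[str] = []
    n_agree = 0
    n_compared = 0
    for call in calls:
        if call.sample_id not in reference:
            missing.append(call.sample_id)
            continue
        n_compared += 1
        ref = reference[call.sample_id]
        if call.final_call == ref:
            n_agree += 1
        else:
            discordant.append((call.sample_id, call.call_string, format_call(ref)))
    return ConcordanceReport(
        n_compared=n_compared,
        n_agree=n_agree,
        discordant=tuple(discordant),
        missing_reference=tuple(missing),
    )
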