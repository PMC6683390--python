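"""Domain vocabulary: HPA systems, genotypes, donors, beads, specificities.

Every HPA system is modelled as biallelic (alleles ``a`` and ``b``); a donor's
zygosity at a system is one of ``aa``, ``ab``, ``bb``.  Antigen *carriage* is
the relation everything downstream queries: a donor carries allele ``a`` at a
system iff the zygosity contains the letter ``a`` (heterozygotes carry both).
Antigen dosage is deliberately ignored — heterozygous and homozygous carriers
predict reactivity identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

ZYGOSITIES = ("aa", "ab", "bb")
ALLELES = ("a", "b")

#: bead roles
HPA_CAPTURE = "hpa_capture"
HLA_CAPTURE = "hla_capture"
POSITIVE_CONTROL = "positive_control"
BEAD_ROLES = (HPA_CAPTURE, HLA_CAPTURE, POSITIVE_CONTROL)


class PanelError(ValueError):
    """Invalid panel definition or query against it."""


def normalize_zygosity(token: str) -> str:
    """Normalize a genotype token to one of ``aa``/``ab``/``bb``.

    Accepts case-insensitive input and the slashed dialect (``a/b``); allele
    order is canonicalized (``ba`` -> ``ab``).
    """
    cleaned = "".join(sorted(token.strip().lower().replace("/", "")))
    if cleaned not in ZYGOSITIES:
        raise PanelError(
            f"invalid zygosity token {token!r}: expected one of {ZYGOSITIES} "
            "(optionally slashed, any case)"
        )
    return cleaned


@dataclass(frozen=True)
class HpaGenotype:
    """One donor's zygosity at one HPA system."""

    system: str
    zygosity: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "zygosity", normalize_zygosity(self.zygosity))

    def carries(self, allele: str) -> bool:
        if allele not in ALLELES:
            raise PanelError(f"unknown allele {allele!r}: expected 'a' or 'b'")
        return allele in self.zygosity


@dataclass(frozen=True)
class Donor:
    """A genotyped panel platelet donor."""

    donor_id: str
    genotypes: Mapping[str, HpaGenotype]

    def __post_init__(self) -> None:
        for system, gt in self.genotypes.items():
            if gt.system != system:
                raise PanelError(
                    f"donor {self.donor_id}: genotype keyed {system!r} "
                    f"declares system {gt.system!r}"
                )

    def genotype(self, system: str) -> HpaGenotype:
        try:
            return self.genotypes[system]
        except KeyError:
            raise PanelError(
                f"donor {self.donor_id} has no genotype for system {system!r}"
            ) from None


def carries(donor: Donor, system: str, allele: str) -> bool:
    """True iff ``donor``'s zygosity at ``system`` contains ``allele``."""
    return donor.genotype(system).carries(allele)


@dataclass(frozen=True)
class Specificity:
    """An antibody specificity: anti-HLA (class I) or anti-HPA-<system><allele>."""

    kind: str  # "anti-HPA" | "anti-HLA"
    system: str | None = None
    allele: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "anti-HLA":
            if self.system is not None or self.allele is not None:
                raise PanelError("anti-HLA specificity carries no system/allele")
        elif self.kind == "anti-HPA":
            if self.system is None or self.allele not in ALLELES:
                raise PanelError(
                    f"anti-HPA specificity needs a system and allele in {ALLELES}"
                )
        else:
            raise PanelError(f"unknown specificity kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "anti-HLA":
            return "anti-HLA"
        return f"anti-{self.system}{self.allele}"

    def __str__(self) -> str:
        return self.label

    def sort_key(self) -> tuple:
        return (self.kind != "anti-HLA", self.system or "", self.allele or "")

    @classmethod
    def hpa(cls, system: str, allele: str) -> "Specificity":
        return cls("anti-HPA", system, allele)


ANTI_HLA = Specificity("anti-HLA")


def parse_specificity(text: str) -> Specificity:
    """Parse one ``anti-HLA`` / ``anti-HPA-3b`` style token (case-insensitive)."""
    token = text.strip()
    low = token.lower()
    if low in ("anti-hla", "anti-hla-i", "anti-hla class i"):
        return ANTI_HLA
    if low.startswith("anti-hpa-"):
        body = token[len("anti-hpa-"):].strip()
        if body and body[-1].lower() in ALLELES:
            system = f"HPA-{body[:-1]}"
            if body[:-1].isdigit() or body[:-1].rstrip("w").isdigit():
                return Specificity.hpa(system, body[-1].lower())
    raise PanelError(f"cannot parse specificity token {text!r}")


def parse_call_string(text: str) -> frozenset[Specificity]:
    """Parse a ``Anti-HLA + anti-HPA-2b`` style call into a specificity set.

    ``Negative`` / empty strings parse to the empty set.  The dialect is
    strict: tokens joined by ``+``, each an ``anti-…`` token.
    """
    stripped = text.strip()
    if not stripped or stripped.lower() in ("negative", "none", "-"):
        return frozenset()
    return frozenset(parse_specificity(tok) for tok in stripped.split("+"))


def format_call(specs: Iterable[Specificity]) -> str:
    """Canonical rendering: anti-HLA first, then anti-HPA by system/allele."""
    ordered = sorted(specs, key=Specificity.sort_key)
    if not ordered:
        return "Negative"
    parts = [s.label for s in ordered]
    parts[0] = "A" + parts[0][1:]  # leading capital, matching report style
    return " + ".join(parts)


@dataclass(frozen=True)
class Bead:
    """One capture bead: the glycoprotein it captures and the HPA systems on it."""

    bead_id: str
    bead_code: str
    target: str
    systems: tuple[str, ...] = ()
    role: str = HPA_CAPTURE
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.role not in BEAD_ROLES:
            raise PanelError(
                f"bead {self.bead_id}: role {self.role!r} not in {BEAD_ROLES}"
            )
        if self.role == HLA_CAPTURE and self.systems:
            raise PanelError(f"bead {self.bead_id}: hla_capture beads carry no HPA systems")
        object.__setattr__(self, "systems", tuple(self.systems))


def candidate_specificities(bead: Bead) -> frozenset[Specificity]:
    """All specificities a bead can in principle report.

    An HLA-capture bead reports only anti-HLA.  A glycoprotein bead reports
    both alleles of every HPA system resident on its target.
    """
    if bead.role == POSITIVE_CONTROL:
        raise PanelError(
            f"bead {bead.bead_id} is a positive control; it has no candidate specificities"
        )
    if bead.role == HLA_CAPTURE:
        return frozenset({ANTI_HLA})
    return frozenset(
        Specificity.hpa(system, allele)
        for system in bead.systems
        for allele in ALLELES
    )


@dataclass(frozen=True)
class BeadPanel:
    """Ordered collection of bead definitions."""

    beads: tuple[Bead, ...]

    def __post_init__(self) -> None:
        ids = [b.bead_id for b in self.beads]
        if len(set(ids)) != len(ids):
            raise PanelError(f"duplicate bead ids in panel: {ids}")
        object.__setattr__(self, "beads", tuple(self.beads))

    def __iter__(self):
        return iter(self.beads)

    def bead(self, bead_id: str) -> Bead:
        for b in self.beads:
            if b.bead_id == bead_id:
                return b
        raise PanelError(f"unknown bead id {bead_id!r}")

    @property
    def active(self) -> tuple[Bead, ...]:
        return tuple(b for b in self.beads if b.enabled)

    @property
    def active_hpa(self) -> tuple[Bead, ...]:
        return tuple(b for b in self.active if b.role == HPA_CAPTURE)

    @property
    def hla_bead(self) -> Bead | None:
        for b in self.active:
            if b.role == HLA_CAPTURE:
                return b
        return None

    def systems(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.beads:
            for s in b.systems:
                seen.setdefault(s)
        return tuple(seen)


@dataclass(frozen=True)
class DonorPanel:
    """Ordered, genotyped donor collection — the combinatorial backbone of inference."""

    donors: tuple[Donor, ...]

    def __post_init__(self) -> None:
        if not self.donors:
            raise PanelError("donor panel must be non-empty")
        ids = [d.donor_id for d in self.donors]
        if len(set(ids)) != len(ids):
            raise PanelError(f"duplicate donor ids: {ids}")
        systems = set(self.donors[0].genotypes)
        for d in self.donors[1:]:
            if set(d.genotypes) != systems:
                raise PanelError(
                    f"donor {d.donor_id} genotyped for {sorted(d.genotypes)}, "
                    f"expected {sorted(systems)}"
                )
        object.__setattr__(self, "donors", tuple(self.donors))

    def __iter__(self):
        return iter(self.donors)

    def __len__(self) -> int:
        return len(self.donors)

    @property
    def donor_ids(self) -> tuple[str, ...]:
        return tuple(d.donor_id for d in self.donors)

    def donor(self, donor_id: str) -> Donor:
        for d in self.donors:
            if d.donor_id == donor_id:
                return d
        raise PanelError(f"unknown donor id {donor_id!r}")

    @property
    def systems(self) -> tuple[str, ...]:
        return tuple(self.donors[0].genotypes)

    def carriers(self, system: str, allele: str) -> frozenset[str]:
        return frozenset(
            d.donor_id for d in self.donors if carries(d, system, allele)
        )

    def without(self, donor_id: str) -> "DonorPanel":
        return replace(
            self, donors=tuple(d for d in self.donors if d.donor_id != donor_id)
        )


@dataclass(frozen=True)
class UninformativeSpecificity:
    """A specificity the panel cannot interrogate both ways.

    Without at least one carrier the specificity can never produce a reactive
    donor; without at least one non-carrier an all-reactive pattern cannot
    distinguish it from other whole-panel explanations.
    """

    specificity: Specificity
    reason: str  # "no_carrier" | "no_noncarrier"


def uninformative_specificities(
    donor_panel: DonorPanel, bead_panel: BeadPanel
) -> tuple[UninformativeSpecificity, ...]:
    """Structural limitations of a donor panel for the active HPA beads."""
    out: list[UninformativeSpecificity] = []
    for bead in bead_panel.active_hpa:
        for spec in sorted(candidate_specificities(bead), key=Specificity.sort_key):
            carriers = donor_panel.carriers(spec.system, spec.allele)
            if not carriers:
                out.append(UninformativeSpecificity(spec, "no_carrier"))
            elif len(carriers) == len(donor_panel):
                out.append(UninformativeSpecificity(spec, "no_noncarrier"))
    return tuple(out)


def validate_panels(donor_panel: DonorPanel, bead_panel: BeadPanel) -> None:
    """Cross-check bead systems against the donor genotype registry.

    Raises on a bead referencing an unregistered system; logs a warning per
    uninformative specificity (a panel-design smell, not an error).
    """
    registered = set(donor_panel.systems)
    for bead in bead_panel:
        for system in bead.systems:
            if system not in registered:
                raise PanelError(
                    f"bead {bead.bead_id} references system {system!r} absent "
                    f"from the donor genotype table (registered: {sorted(registered)})"
                )
    for item in uninformative_specificities(donor_panel, bead_panel):
        logger.warning(
            "uninformative specificity=%s reason=%s", item.specificity, item.reason
        )


def load_panel(genotype_table, bead_config) -> tuple[DonorPanel, BeadPanel]:
    """Load and cross-validate donor and bead panels from their file formats.

    Thin wrapper over :func:`lumipanel.io.read_genotypes` and
    :func:`lumipanel.io.read_beads` followed by :func:`validate_panels`.
    """
    from lumipanel import io  # deferred: io imports this module

    donor_panel = io.read_genotypes(genotype_table)
    bead_panel = io.read_beads(bead_config)
    validate_panels(donor_panel, bead_panel)
    return donor_panel, bead_panel
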