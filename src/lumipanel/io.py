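"""File formats, packaged fixtures, report writing, and the pipeline runner.

All tabular formats are UTF-8 CSV with a required header and a plain decimal
point (thousands separators are rejected).  Writers emit a canonical form —
stable row order, shortest-round-trip floats — so read ∘ write is the
identity on canonical files and identical inputs yield identical bytes.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from lumipanel.deconvolution import (
    ConcordanceReport,
    PriorTable,
    SpecificityCall,
    call_sample,
    concordance,
)
from lumipanel.panel_model import (
    Bead,
    BeadPanel,
    Donor,
    DonorPanel,
    HpaGenotype,
    PanelError,
    format_call,
    parse_call_string,
    validate_panels,
)
from lumipanel.reactivity import (
    BeadCutoff,
    CutoffSet,
    MfiMatrix,
    ReactivityPattern,
    call_reactivity,
    compute_cutoffs,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


class SchemaError(ValueError):
    """A file failed validation; carries file/line/column context."""

    def __init__(self, message: str, file: str | None = None,
                 line: int | None = None, column: str | None = None):
        self.file = file
        self.line = line
        self.column = column
        where = []
        if file is not None:
            where.append(f"file={file}")
        if line is not None:
            where.append(f"line={line}")
        if column is not None:
            where.append(f"column={column}")
        suffix = f" [{' '.join(where)}]" if where else ""
        super().__init__(message + suffix)


def _format_number(value: float) -> str:
    """Canonical float rendering: shortest repr, integral values without .0."""
    text = repr(float(value))
    return text[:-2] if text.endswith(".0") else text


def _parse_number(text: str, file: str, line: int, column: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise SchemaError(
            f"non-numeric value {text!r} (thousands separators are not accepted)",
            file=file, line=line, column=column,
        ) from None


# ---------------------------------------------------------------------------
# packaged fixtures

def fixture_path(name: str) -> Path:
    """Path to a packaged data file (e.g. ``donors.csv``, ``beads.yaml``)."""
    return Path(str(resources.files("lumipanel").joinpath("data", name)))


def load_clinical_fixture() -> tuple[DonorPanel, BeadPanel, MfiMatrix, CutoffSet]:
    """The packaged clinical dataset: panels, the 9-sample MFI table, cutoffs."""
    donors = read_genotypes(fixture_path("donors.csv"))
    beads = read_beads(fixture_path("beads.yaml"))
    validate_panels(donors, beads)
    mfi = read_mfi(fixture_path("clinical_mfi.csv"))
    cutoffs = read_cutoffs(fixture_path("cutoffs.csv"))
    return donors, beads, mfi, cutoffs


def load_expected_calls():
    """Published interpretation of the clinical fixture, sample -> call set."""
    return read_reference_calls(fixture_path("expected_calls.csv"), column="call")


# ---------------------------------------------------------------------------
# genotype table

def read_genotypes(path) -> DonorPanel:
    """CSV ``donor_id,<system>,...`` with zygosity cells; one row per donor."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "donor_id" not in reader.fieldnames:
            raise SchemaError("genotype table needs a 'donor_id' column", file=str(path))
        systems = [c for c in reader.fieldnames if c != "donor_id"]
        if not systems:
            raise SchemaError("genotype table declares no HPA systems", file=str(path))
        donors: list[Donor] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            donor_id = (row["donor_id"] or "").strip()
            if not donor_id:
                raise SchemaError("empty donor_id", file=str(path), line=lineno)
            if donor_id in seen:
                raise SchemaError(
                    f"duplicate donor_id {donor_id!r}", file=str(path), line=lineno
                )
            seen.add(donor_id)
            genotypes = {}
            for system in systems:
                try:
                    genotypes[system] = HpaGenotype(system, row[system])
                except PanelError as exc:
                    raise SchemaError(
                        str(exc), file=str(path), line=lineno, column=system
                    ) from None
            donors.append(Donor(donor_id=donor_id, genotypes=genotypes))
    if not donors:
        raise SchemaError("genotype table contains no donors", file=str(path))
    return DonorPanel(tuple(donors))


def write_genotypes(panel: DonorPanel, path) -> None:
    path = Path(path)
    systems = list(panel.systems)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["donor_id", *systems])
        for donor in panel:
            writer.writerow(
                [donor.donor_id, *(donor.genotypes[s].zygosity for s in systems)]
            )


# ---------------------------------------------------------------------------
# bead config

def read_beads(path) -> BeadPanel:
    """YAML bead config: a ``beads`` list of id/code/target/systems/role/enabled."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise SchemaError(f"bead config is not valid YAML: {exc}", file=str(path)) from None
    if not isinstance(doc, dict) or "beads" not in doc:
        raise SchemaError("bead config needs a top-level 'beads' list", file=str(path))
    beads = []
    for i, entry in enumerate(doc["beads"]):
        try:
            beads.append(
                Bead(
                    bead_id=str(entry["id"]),
                    bead_code=str(entry.get("code", "")),
                    target=str(entry.get("target", "")),
                    systems=tuple(entry.get("systems") or ()),
                    role=str(entry.get("role", "hpa_capture")),
                    enabled=bool(entry.get("enabled", True)),
                )
            )
        except (KeyError, PanelError) as exc:
            raise SchemaError(
                f"bead entry #{i + 1}: {exc}", file=str(path)
            ) from None
    try:
        return BeadPanel(tuple(beads))
    except PanelError as exc:
        raise SchemaError(str(exc), file=str(path)) from None


def write_beads(panel: BeadPanel, path) -> None:
    doc = {
        "beads": [
            {
                "id": b.bead_id,
                "code": b.bead_code,
                "target": b.target,
                "systems": list(b.systems),
                "role": b.role,
                "enabled": b.enabled,
            }
            for b in panel
        ]
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=None),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# MFI table

def read_mfi(path) -> MfiMatrix:
    """CSV ``sample_id,donor_id,bead_id,mfi[,role]``.

    MFIs are parsed strictly: plain decimal point, no thousands separators.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "donor_id", "bead_id", "mfi"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SchemaError(
                f"MFI table needs columns {sorted(required)}, "
                f"found {reader.fieldnames}",
                file=str(path),
            )
        has_role = "role" in reader.fieldnames
        rows = []
        for lineno, row in enumerate(reader, start=2):
            mfi = _parse_number(row["mfi"], str(path), lineno, "mfi")
            rec = {
                "sample_id": row["sample_id"].strip(),
                "donor_id": row["donor_id"].strip(),
                "bead_id": row["bead_id"].strip(),
                "mfi": mfi,
            }
            if has_role:
                rec["role"] = row["role"].strip()
            rows.append(rec)
    if not rows:
        raise SchemaError("MFI table contains no rows", file=str(path))
    try:
        return MfiMatrix(pd.DataFrame(rows))
    except ValueError as exc:
        raise SchemaError(str(exc), file=str(path)) from None


def write_mfi(mfi: MfiMatrix, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "donor_id", "bead_id", "mfi", "role"])
        for row in mfi.frame.itertuples(index=False):
            writer.writerow(
                [row.sample_id, row.donor_id, row.bead_id,
                 _format_number(row.mfi), row.role]
            )


# ---------------------------------------------------------------------------
# cutoffs

def read_cutoffs(path) -> CutoffSet:
    """CSV ``bead_id,neg_mean,neg_sd,cutoff,n_controls`` (stats optional)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "bead_id" not in reader.fieldnames \
                or "cutoff" not in reader.fieldnames:
            raise SchemaError(
                "cutoff table needs 'bead_id' and 'cutoff' columns", file=str(path)
            )
        cutoffs = []
        for lineno, row in enumerate(reader, start=2):
            def opt(column: str, cast=float):
                value = (row.get(column) or "").strip()
                if not value:
                    return None
                return cast(_parse_number(value, str(path), lineno, column))
            try:
                cutoffs.append(
                    BeadCutoff(
                        bead_id=row["bead_id"].strip(),
                        cutoff=_parse_number(row["cutoff"], str(path), lineno, "cutoff"),
                        neg_mean=opt("neg_mean"),
                        neg_sd=opt("neg_sd"),
                        n_controls=opt("n_controls", int),
                        donor_id=(row.get("donor_id") or "").strip() or None,
                    )
                )
            except SchemaError:
                raise
            except ValueError as exc:
                raise SchemaError(str(exc), file=str(path), line=lineno) from None
    if not cutoffs:
        raise SchemaError("cutoff table contains no rows", file=str(path))
    try:
        return CutoffSet(tuple(cutoffs))
    except ValueError as exc:
        raise SchemaError(str(exc), file=str(path)) from None


def write_cutoffs(cutoffs: CutoffSet, path) -> None:
    path = Path(path)
    per_donor = any(c.donor_id for c in cutoffs)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        header = ["bead_id", "neg_mean", "neg_sd", "cutoff", "n_controls"]
        if per_donor:
            header.append("donor_id")
        writer.writerow(header)
        for c in cutoffs:
            row = [
                c.bead_id,
                _format_number(c.neg_mean) if c.neg_mean is not None else "",
                _format_number(c.neg_sd) if c.neg_sd is not None else "",
                _format_number(c.cutoff),
                str(c.n_controls) if c.n_controls is not None else "",
            ]
            if per_donor:
                row.append(c.donor_id or "")
            writer.writerow(row)


# ---------------------------------------------------------------------------
# reference calls

def read_reference_calls(path, column: str = "reference_call"):
    """CSV ``sample_id,<column>`` of ``Anti-HLA + anti-HPA-2b`` style strings."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames \
                or column not in reader.fieldnames:
            raise SchemaError(
                f"reference table needs 'sample_id' and {column!r} columns",
                file=str(path),
            )
        out = {}
        for lineno, row in enumerate(reader, start=2):
            sample_id = row["sample_id"].strip()
            if sample_id in out:
                raise SchemaError(
                    f"duplicate sample_id {sample_id!r}", file=str(path), line=lineno
                )
            try:
                out[sample_id] = parse_call_string(row[column])
            except PanelError as exc:
                raise SchemaError(
                    str(exc), file=str(path), line=lineno, column=column
                ) from None
    return out


# ---------------------------------------------------------------------------
# reports

def call_report_dict(
    calls: Iterable[SpecificityCall],
    cutoffs: CutoffSet | None = None,
    concordance_report: ConcordanceReport | None = None,
) -> dict:
    """Stable-ordered JSON-serializable report for a run."""
    calls = list(calls)
    samples = {}
    for call in sorted(calls, key=lambda c: c.sample_id):
        samples[call.sample_id] = {
            "final_call": call.call_string,
            "specificities": sorted(s.label for s in call.final_call),
            "hla_positive": call.hla_positive,
            "negative": call.negative,
            "flags": [f.as_dict() for f in call.flags],
            "beads": {
                bead_id: {
                    "reactive": sorted(b.reactive),
                    "nonreactive": sorted(b.nonreactive),
                    "borderline": sorted(b.borderline),
                    "unexplained": b.unexplained,
                    "borderline_only": b.borderline_only,
                    "candidate_sets": [
                        {
                            "specificities": list(r.labels),
                            "cardinality": r.cardinality,
                            "prior_score": r.prior_score,
                            "rank": r.rank,
                        }
                        for r in b.candidate_sets
                    ],
                }
                for bead_id, b in sorted(call.beads.items())
            },
        }
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "samples": samples}
    if calls:
        report["structural_limitations"] = [
            {"specificity": u.specificity.label, "reason": u.reason}
            for u in calls[0].structural_limitations
        ]
    if cutoffs is not None:
        report["cutoffs"] = {
            (c.bead_id if c.donor_id is None else f"{c.bead_id}/{c.donor_id}"):
                c.cutoff
            for c in cutoffs
        }
    if concordance_report is not None:
        report["concordance"] = {
            "n_compared": concordance_report.n_compared,
            "n_agree": concordance_report.n_agree,
            "percent_agreement": concordance_report.percent_agreement,
            "discordant": [list(d) for d in concordance_report.discordant],
            "missing_reference": list(concordance_report.missing_reference),
        }
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )


def write_summary_csv(calls: Iterable[SpecificityCall], path) -> None:
    """Flat ``sample_id,final_call,flags`` summary."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "final_call", "flags"])
        for call in sorted(calls, key=lambda c: c.sample_id):
            flag_text = ";".join(
                f.kind + (f":{f.bead_id}" if f.bead_id else "") for f in call.flags
            )
            writer.writerow([call.sample_id, call.call_string, flag_text])


def validate_report(report: dict) -> None:
    """Structural check of a report dict against the published schema."""
    schema = json.loads(fixture_path("report.schema.json").read_text(encoding="utf-8"))
    _check_schema(report, schema, "$")


def _check_schema(value, schema: dict, path: str) -> None:
    # minimal structural validator covering the subset of JSON Schema the
    # report schema uses (type / required / properties / additionalProperties)
    expected = schema.get("type")
    type_map = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "integer": int, "boolean": bool,
    }
    if expected and not isinstance(value, type_map[expected]):
        raise SchemaError(f"{path}: expected {expected}, got {type(value).__name__}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise SchemaError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        extra = schema.get("additionalProperties")
        for key, sub in value.items():
            if key in props:
                _check_schema(sub, props[key], f"{path}.{key}")
            elif isinstance(extra, dict):
                _check_schema(sub, extra, f"{path}.{key}")
    elif expected == "array":
        items = schema.get("items")
        if isinstance(items, dict):
            for i, sub in enumerate(value):
                _check_schema(sub, items, f"{path}[{i}]")


# ---------------------------------------------------------------------------
# pipeline

@dataclass(frozen=True)
class RunConfig:
    """End-to-end run parameters (paths resolved, options validated)."""

    mfi: Path
    genotypes: Path
    beads: Path
    cutoffs: Path | None = None  # exactly one of cutoffs / controls-in-mfi
    priors: Path | None = None
    reference: Path | None = None
    grey_factor: float = 1.25
    max_set_size: int = 2
    sd_ddof: int = 1
    per_donor_cutoffs: bool = False


@dataclass(frozen=True)
class PipelineResult:
    calls: tuple[SpecificityCall, ...]
    cutoffs: CutoffSet
    pattern: ReactivityPattern
    concordance: ConcordanceReport | None

    def report(self) -> dict:
        return call_report_dict(
            list(self.calls), cutoffs=self.cutoffs,
            concordance_report=self.concordance,
        )


def reproduce_clinical_fixture() -> tuple[
    "PipelineResult", dict, tuple[tuple[str, tuple[str, str]], ...]
]:
    """Run the packaged clinical fixture end-to-end and diff the calls.

    Returns the pipeline result, the expected call sets, and a tuple of
    ``(sample_id, (our_call, expected_call))`` mismatches (empty on success).
    """
    config = RunConfig(
        mfi=fixture_path("clinical_mfi.csv"),
        genotypes=fixture_path("donors.csv"),
        beads=fixture_path("beads.yaml"),
        cutoffs=fixture_path("cutoffs.csv"),
        reference=fixture_path("reference_calls.csv"),
    )
    result = run_pipeline(config)
    expected = load_expected_calls()
    mismatches = tuple(
        (c.sample_id, (c.call_string, format_call(expected[c.sample_id])))
        for c in result.calls
        if c.sample_id in expected and c.final_call != expected[c.sample_id]
    )
    return result, expected, mismatches


def read_priors(path) -> PriorTable:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise SchemaError("priors file must map specificity labels to weights",
                          file=str(path))
    weights = dict(PriorTable.default().weights)
    weights.update({str(k): float(v) for k, v in doc.items()})
    return PriorTable(weights)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load panels -> cutoffs -> reactivity -> deconvolution -> concordance."""
    donor_panel = read_genotypes(config.genotypes)
    bead_panel = read_beads(config.beads)
    validate_panels(donor_panel, bead_panel)
    mfi = read_mfi(config.mfi)
    mfi.validate_against(donor_panel, bead_panel)

    has_controls = (mfi.frame["role"] == "negative_control").any()
    if config.cutoffs is not None:
        if has_controls:
            raise SchemaError(
                "supply either a cutoff file or negative-control samples, not both"
            )
        cutoffs = read_cutoffs(config.cutoffs)
    elif has_controls:
        cutoffs = compute_cutoffs(
            mfi.with_role("negative_control"),
            beads=[b.bead_id for b in bead_panel.active
                   if b.bead_id in mfi.bead_ids],
            ddof=config.sd_ddof,
            per_donor=config.per_donor_cutoffs,
        )
    else:
        raise SchemaError(
            "no cutoff file and no negative-control samples in the MFI table"
        )

    priors = read_priors(config.priors) if config.priors else PriorTable.default()
    priors.validate_coverage(bead_panel)

    tests = MfiMatrix(mfi.frame[mfi.frame["role"] == "test"])
    pattern = call_reactivity(
        tests, cutoffs, donor_panel=donor_panel, grey_factor=config.grey_factor
    )
    calls = tuple(
        call_sample(
            sample_id, pattern, donor_panel, bead_panel,
            priors=priors, max_set_size=config.max_set_size,
        )
        for sample_id in tests.sample_ids
    )

    report = None
    if config.reference is not None:
        reference = read_reference_calls(config.reference)
        report = concordance(list(calls), reference)
    return PipelineResult(
        calls=calls, cutoffs=cutoffs, pattern=pattern, concordance=report
    )
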