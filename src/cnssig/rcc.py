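"""NanoString CodeSet modeling and RCC file reading/writing.

An nCounter lane is stored as a sectioned text file (RCC): ``<Header>``,
``<Sample_Attributes>``, ``<Lane_Attributes>`` and a ``<Code_Summary>``
section whose body is CSV with columns ``CodeClass,Name,Accession,Count``.
The dialect written here is the common tag-delimited flavor (file version
1.7) and is fixed bit-exactly so generated fixtures round-trip.

The :class:`CodeSet` describes the custom probe panel: per-entity marker
probes (with brain-compartment applicability), housekeeping genes
(ACTB, GAPDH, LDHA), a glioma-contrast panel (GFAP, OLIG2, PMP2) and
positive/negative control probes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, RCCParseError
from .matrix import COMPARTMENTS, INFRATENTORIAL, SUPRATENTORIAL

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")


@dataclass
class CodeSet:
    """Custom probe panel definition.

    ``entities`` maps entity name -> {compartment -> list of marker probe
    names}. An entity absent from a compartment's mapping is not detectable
    (and not callable) there.
    """

    name: str
    entities: dict[str, dict[str, list[str]]]
    housekeeping: list[str] = field(default_factory=lambda: ["ACTB", "GAPDH", "LDHA"])
    glioma_panel: list[str] = field(default_factory=lambda: ["GFAP", "OLIG2", "PMP2"])
    positive_controls: list[str] = field(
        default_factory=lambda: [f"POS_{c}" for c in "ABCDEF"]
    )
    negative_controls: list[str] = field(
        default_factory=lambda: [f"NEG_{c}" for c in "ABCDEFGH"]
    )

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if not self.housekeeping:
            raise ConfigurationError("housekeeping list must be nonempty")
        for entity, panels in self.entities.items():
            if not any(panels.get(c) for c in panels):
                raise ConfigurationError(f"entity {entity!r} has no marker probes")
            for comp in panels:
                if comp not in COMPARTMENTS:
                    raise ConfigurationError(
                        f"unknown compartment {comp!r} for entity {entity!r}"
                    )
        # Probe names must be unique across categories (marker probes of
        # different entities, housekeeping, glioma panel, controls).
        seen: dict[str, str] = {}
        for cat, probes in self._categories():
            for p in probes:
                if p in seen and seen[p] != cat:
                    raise ConfigurationError(
                        f"probe {p!r} appears in both {seen[p]!r} and {cat!r}"
                    )
                if p in seen and cat.startswith("markers:") and seen[p] == cat:
                    raise ConfigurationError(f"duplicate probe {p!r} in {cat!r}")
                seen[p] = cat

    def _categories(self):
        for entity, panels in self.entities.items():
            union: list[str] = []
            for comp in sorted(panels):
                for p in panels[comp]:
                    if p not in union:
                        union.append(p)
            yield f"markers:{entity}", union
        yield "housekeeping", self.housekeeping
        yield "glioma", self.glioma_panel
        yield "positive", self.positive_controls
        yield "negative", self.negative_controls

    # -- queries -----------------------------------------------------------
    def markers_for(self, entity: str, compartment: str) -> list[str]:
        """Marker probes of ``entity`` applicable in ``compartment`` ([] if none)."""
        return list(self.entities.get(entity, {}).get(compartment, []))

    def marker_union(self, entity: str) -> list[str]:
        """All marker probes of ``entity`` across compartments (stable order)."""
        out: list[str] = []
        for comp in sorted(self.entities.get(entity, {})):
            for p in self.entities[entity][comp]:
                if p not in out:
                    out.append(p)
        return out

    def entities_in(self, compartment: str) -> list[str]:
        return [e for e in self.entities if self.entities[e].get(compartment)]

    def endogenous_probes(self) -> list[str]:
        """All non-control, non-housekeeping probes: entity markers + glioma panel."""
        out: list[str] = []
        for entity in self.entities:
            for p in self.marker_union(entity):
                if p not in out:
                    out.append(p)
        out.extend(p for p in self.glioma_panel if p not in out)
        return out

    def analysis_probes(self, compartment: str) -> list[str]:
        """Probes clustered in a compartment: applicable marker panels + glioma panel."""
        out: list[str] = []
        for entity in self.entities_in(compartment):
            for p in self.markers_for(entity, compartment):
                if p not in out:
                    out.append(p)
        out.extend(p for p in self.glioma_panel if p not in out)
        return out

    def code_class_of(self, probe: str) -> str:
        if probe in self.positive_controls:
            return "Positive"
        if probe in self.negative_controls:
            return "Negative"
        if probe in self.housekeeping:
            return "Housekeeping"
        return "Endogenous"

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "entities": {e: dict(p) for e, p in self.entities.items()},
            "housekeeping": list(self.housekeeping),
            "glioma_panel": list(self.glioma_panel),
            "positive_controls": list(self.positive_controls),
            "negative_controls": list(self.negative_controls),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "CodeSet":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CodeSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_codeset() -> CodeSet:
    """The four-entity diagnostic CodeSet with compartment applicability.

    NB-FOXR2 and EFT-CIC tumors occur supratentorially only, so their
    panels are restricted to that compartment. HGNET-BCOR and HGNET-MN1
    panels differ between compartments: probes over-expressed by posterior
    fossa ependymomas/medulloblastomas (EMX1, PRDM6) are dropped
    infratentorially, RTN4RL1 is used infratentorially only, and the two
    MN1 probes with poor infratentorial hybridization (RBP4, PRRX2) are
    excluded everywhere.
    """
    return CodeSet(
        name="cns_four_entity_v1",
        entities={
            "HGNET-BCOR": {
                SUPRATENTORIAL: ["BCOR", "EMX1", "PRDM6", "SHISA8", "MNX1", "MMP15"],
                INFRATENTORIAL: ["SHISA8", "MNX1", "MMP15", "RTN4RL1"],
            },
            "HGNET-MN1": {
                SUPRATENTORIAL: ["BEND2", "MUM1", "SHOX", "APCDD1L", "FAM3B", "ECHS1"],
                INFRATENTORIAL: ["BEND2", "SHOX", "APCDD1L"],
            },
            "NB-FOXR2": {
                SUPRATENTORIAL: ["FOXR2", "DNAH2", "SOX10", "FAM163A"],
            },
            "EFT-CIC": {
                SUPRATENTORIAL: ["MYO1D", "CES1", "SCARA5", "CAMK1G", "SHC4", "ETV4"],
            },
        },
    )


@dataclass
class RCCRecord:
    code_class: str
    name: str
    accession: str
    count: int


@dataclass
class RCCSample:
    """One nCounter lane: attributes plus per-probe counts."""

    sample_id: str
    lane_attributes: dict[str, str] = field(default_factory=dict)
    sample_attributes: dict[str, str] = field(default_factory=dict)
    records: list[RCCRecord] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        for rec in self.records:
            if not isinstance(rec.count, int) or rec.count < 0:
                raise ConfigurationError(
                    f"probe {rec.name!r}: count must be a non-negative integer"
                )
            if rec.name in seen:
                raise ConfigurationError(f"duplicate probe {rec.name!r} in sample")
            seen.add(rec.name)

    def counts(self) -> pd.Series:
        return pd.Series(
            {r.name: r.count for r in self.records}, name=self.sample_id, dtype=int
        )

    def probe_names(self) -> list[str]:
        return [r.name for r in self.records]


_HEADER_FIELDS = [("FileVersion", "1.7"), ("SoftwareVersion", "4.0.0.3")]
_SAMPLE_ATTR_ORDER = ["ID", "Owner", "Comments", "Date", "GeneRLF", "SystemAPF"]
_LANE_ATTR_ORDER = [
    "ID",
    "FovCount",
    "FovCounted",
    "ScannerID",
    "StagePosition",
    "BindingDensity",
    "CartridgeID",
]


def _csv_line(fields) -> str:
    buf = io.StringIO()
    csv.writer(buf, lineterminator="").writerow(fields)
    return buf.getvalue()


def write_rcc(sample: RCCSample, path) -> None:
    """Write one lane in the sectioned RCC dialect (stable field order)."""
    sample.validate()
    lines: list[str] = ["<Header>"]
    lines += [_csv_line(kv) for kv in _HEADER_FIELDS]
    lines.append("</Header>")

    lines.append("<Sample_Attributes>")
    sattr = dict(sample.sample_attributes)
    sattr.setdefault("ID", sample.sample_id)
    sattr["ID"] = sample.sample_id
    for key in _SAMPLE_ATTR_ORDER:
        lines.append(_csv_line([key, sattr.get(key, "")]))
    lines.append("</Sample_Attributes>")

    lines.append("<Lane_Attributes>")
    for key in _LANE_ATTR_ORDER:
        lines.append(_csv_line([key, sample.lane_attributes.get(key, "")]))
    lines.append("</Lane_Attributes>")

    lines.append("<Code_Summary>")
    lines.append("CodeClass,Name,Accession,Count")
    for rec in sample.records:
        lines.append(
            _csv_line([rec.code_class, rec.name, rec.accession, str(rec.count)])
        )
    lines.append("</Code_Summary>")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rcc(path) -> RCCSample:
    """Parse a sectioned RCC file into a validated :class:`RCCSample`.

    Raises :class:`RCCParseError` (with the offending line number) on a
    missing/unterminated section, a malformed or negative count, or a
    duplicate probe name.
    """
    text = Path(path).read_text()
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip("\r")
        if not line.strip():
            continue
        if line.startswith("</"):
            name = line.strip()[2:-1]
            if current != name:
                raise RCCParseError(
                    f"closing tag </{name}> does not match open section "
                    f"{current!r}",
                    line=lineno,
                )
            current = None
            continue
        if line.startswith("<"):
            current = line.strip()[1:-1]
            sections.setdefault(current, [])
            continue
        if current is None:
            raise RCCParseError(f"content outside any section: {line!r}", line=lineno)
        sections[current].append((lineno, line))
    if current is not None:
        raise RCCParseError(f"section <{current}> is not closed (missing </{current}>)")
    for required in ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary"):
        if required not in sections:
            raise RCCParseError(f"missing section <{required}>")

    def _kv(section: str) -> dict[str, str]:
        out = {}
        for lineno, line in sections[section]:
            row = next(csv.reader([line]))
            if len(row) < 1:
                raise RCCParseError(f"malformed row in <{section}>", line=lineno)
            out[row[0]] = row[1] if len(row) > 1 else ""
        return out

    sattr = _kv("Sample_Attributes")
    lattr = _kv("Lane_Attributes")
    sample_id = sattr.get("ID", "")
    if not sample_id:
        raise RCCParseError("Sample_Attributes has no ID")

    records: list[RCCRecord] = []
    seen: set[str] = set()
    body = sections["Code_Summary"]
    if not body:
        rows = []
    else:
        header_lineno, header_line = body[0]
        header = next(csv.reader([header_line]))
        if [h.strip() for h in header] != ["CodeClass", "Name", "Accession", "Count"]:
            raise RCCParseError(
                f"unexpected Code_Summary header {header!r}", line=header_lineno
            )
        rows = body[1:]
    for lineno, line in rows:
        row = next(csv.reader([line]))
        if len(row) != 4:
            raise RCCParseError(
                f"Code_Summary row has {len(row)} fields, expected 4", line=lineno
            )
        code_class, name, accession, count_str = row
        try:
            count = int(count_str)
        except ValueError:
            raise RCCParseError(
                f"non-integer count {count_str!r} for probe {name!r}", line=lineno
            ) from None
        if count < 0:
            raise RCCParseError(f"negative count for probe {name!r}", line=lineno)
        if name in seen:
            raise RCCParseError(f"duplicate probe {name!r}", line=lineno)
        seen.add(name)
        records.append(RCCRecord(code_class, name, accession, count))

    return RCCSample(
        sample_id=sample_id,
        lane_attributes=lattr,
        sample_attributes=sattr,
        records=records,
    )


def read_rcc_dir(directory) -> list[RCCSample]:
    """Read every ``*.RCC`` / ``*.rcc`` file in a directory, sorted by name."""
    paths = sorted(
        p for p in Path(directory).iterdir() if p.suffix.lower() == ".rcc"
    )
    return [read_rcc(p) for p in paths]


@dataclass
class CountMatrices:
    """Raw count matrix split by code class; sample order preserved."""

    endogenous: pd.DataFrame
    housekeeping: pd.DataFrame
    positive: pd.DataFrame
    negative: pd.DataFrame

    @property
    def samples(self) -> pd.Index:
        return self.endogenous.columns

    def all_counts(self) -> pd.DataFrame:
        return pd.concat(
            [self.endogenous, self.housekeeping, self.positive, self.negative]
        )


def assemble_count_matrix(samples: list[RCCSample], codeset: CodeSet) -> CountMatrices:
    """Stack lanes into probes x samples integer matrices.

    All lanes must carry the identical probe set; a mismatch raises a
    :class:`ConfigurationError` naming the asymmetric probes. Code classes
    are taken from the CodeSet (probe identity is by name).
    """
    if not samples:
        raise ConfigurationError("no samples to assemble")
    ref_probes = set(samples[0].probe_names())
    for s in samples[1:]:
        probes = set(s.probe_names())
        if probes != ref_probes:
            missing = sorted(ref_probes - probes)
            extra = sorted(probes - ref_probes)
            raise ConfigurationError(
                f"probe-set mismatch in sample {s.sample_id!r}: "
                f"missing={missing} extra={extra}"
            )
    counts = pd.concat([s.counts() for s in samples], axis=1)

    def _select(probes: list[str]) -> pd.DataFrame:
        present = [p for p in probes if p in counts.index]
        return counts.loc[present]

    return CountMatrices(
        endogenous=_select(codeset.endogenous_probes()),
        housekeeping=_select(codeset.housekeeping),
        positive=_select(codeset.positive_controls),
        negative=_select(codeset.negative_controls),
    )
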