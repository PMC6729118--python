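"""Read and write CDISC ODM 1.3.x form definitions with UMLS annotations.

Forms are metadata-only ODM documents (Study -> MetaDataVersion -> FormDef /
ItemGroupDef / ItemDef).  UMLS annotations live in item-level ``Alias``
elements whose ``Context`` attribute is one of the accepted alias contexts
(default ``{"UMLS", "UMLS CUI"}``); a postcoordinated code may be encoded
either as one alias carrying a whitespace-separated CUI list or as several
UMLS aliases on the same item — both normalize to one CUI set.

ODM has no standard slot for a form's documentation context, so on write it
is carried as a ``Protocol``-level alias (``Context="DocumentationContext"``)
and on read a sidecar context map always wins over the in-file alias.
"""

from __future__ import annotations

import io
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .concepts import ConceptCode, ConceptError, parse_concept

logger = logging.getLogger(__name__)

__all__ = [
    "ODM_NS",
    "DATATYPES",
    "AnnotatedItem",
    "FormDocument",
    "DialectConfig",
    "Diagnostic",
    "ParseReport",
    "OdmError",
    "OdmParseError",
    "OdmFormatError",
    "read_odm",
    "write_odm",
    "read_corpus",
    "load_context_map",
]

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
XML_LANG = "{http://www.w3.org/XML/1998/namespace}lang"

#: Closed internal datatype set.
DATATYPES = frozenset(
    {"text", "integer", "float", "boolean", "date", "datetime", "codelist"}
)

#: ODM DataType attribute -> internal datatype for non-identity cases.
_ODM_DATATYPE_ALIASES = {"string": "text", "double": "float", "time": "datetime"}

#: Seed set of documentation-context labels (open set; any non-empty label works).
KNOWN_CONTEXTS = (
    "routine",
    "registry",
    "study_crf",
    "eligibility",
    "quality_assurance",
    "recommendation",
    "risk_score",
)

EXCLUSION_REASONS = ("none", "nondistinct", "administrative")


class OdmError(Exception):
    """Base class for ODM reading/writing failures."""


class OdmParseError(OdmError):
    """Malformed XML; message names the offending line where available."""


class OdmFormatError(OdmError):
    """Well-formed XML that is not a usable ODM form definition."""


@dataclass
class AnnotatedItem:
    """One form question, optionally carrying a UMLS concept code."""

    item_id: str
    name: str
    question: str = ""
    datatype: str = "text"
    code: ConceptCode | None = None
    excluded: str = "none"  # none | nondistinct | administrative

    def __post_init__(self) -> None:
        if self.datatype not in DATATYPES:
            raise ValueError(f"unknown datatype {self.datatype!r}")
        if self.excluded not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.excluded!r}")

    @property
    def counted(self) -> bool:
        """True when the item contributes to downstream statistics."""
        return self.excluded == "none"


@dataclass
class FormDocument:
    """One source form: identity, title, documentation context, ordered items."""

    form_id: str
    title: str
    context: str
    items: list[AnnotatedItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.form_id:
            raise ValueError("form_id must be non-empty")
        if not self.context:
            raise ValueError("context label must be non-empty")


@dataclass
class DialectConfig:
    """Knobs for reading third-party ODM files."""

    alias_contexts: tuple[str, ...] = ("UMLS", "UMLS CUI")
    context_alias: str = "DocumentationContext"
    context_override: str | None = None


@dataclass(frozen=True)
class Diagnostic:
    level: str
    file: str
    item_id: str
    message: str


@dataclass
class ParseReport:
    """Aggregated per-file diagnostics from a corpus read."""

    diagnostics: list[Diagnostic] = field(default_factory=list)

    def add(self, level: str, file: str, item_id: str, message: str) -> None:
        diag = Diagnostic(level, file, item_id, message)
        self.diagnostics.append(diag)
        getattr(logger, level if level != "error" else "error", logger.info)(
            "%s item=%s: %s", file, item_id or "-", message
        )

    def errors(self) -> list[Diagnostic]:
        return [d for d in self.diagnostics if d.level == "error"]

    def warnings(self) -> list[Diagnostic]:
        return [d for d in self.diagnostics if d.level == "warning"]

    def __len__(self) -> int:
        return len(self.diagnostics)


def _tag(name: str) -> str:
    return f"{{{ODM_NS}}}{name}"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_all_local(parent: ET.Element, name: str) -> list[ET.Element]:
    return [child for child in parent if _localname(child.tag) == name]


def _source_name(source) -> str:
    if isinstance(source, (str, Path)):
        return str(source)
    return getattr(source, "name", "<stream>")


def read_odm(
    source: str | Path | IO,
    dialect: DialectConfig | None = None,
    report: ParseReport | None = None,
) -> FormDocument:
    """Parse one ODM file into a :class:`FormDocument`.

    Annotation strings failing CUI syntax leave the item unannotated and are
    recorded in ``report`` (never silently dropped).  The documentation
    context is taken from ``dialect.context_override`` if set, else from the
    in-file context alias; if neither exists an :class:`OdmFormatError` is
    raised.
    """
    dialect = dialect or DialectConfig()
    report = report if report is not None else ParseReport()
    name = _source_name(source)

    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        raise OdmParseError(f"{name}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if _localname(root.tag) != "ODM":
        raise OdmFormatError(
            f"{name}: root element is {_localname(root.tag)!r}, expected ODM"
        )

    study = next(iter(_find_all_local(root, "Study")), None)
    if study is None:
        raise OdmFormatError(f"{name}: no Study element")
    mdv = next(iter(_find_all_local(study, "MetaDataVersion")), None)
    if mdv is None:
        raise OdmFormatError(f"{name}: no MetaDataVersion element")

    form_def = next(iter(_find_all_local(mdv, "FormDef")), None)
    item_group_defs = {
        ig.get("OID"): ig for ig in _find_all_local(mdv, "ItemGroupDef")
    }
    item_defs = {idef.get("OID"): idef for idef in _find_all_local(mdv, "ItemDef")}

    # Identity and title
    form_id = (form_def.get("OID") if form_def is not None else None) or study.get(
        "OID"
    )
    if not form_id:
        raise OdmFormatError(f"{name}: neither FormDef nor Study carries an OID")
    title = None
    gv = next(iter(_find_all_local(study, "GlobalVariables")), None)
    if gv is not None:
        study_name = next(iter(_find_all_local(gv, "StudyName")), None)
        if study_name is not None and study_name.text:
            title = study_name.text
    if title is None and form_def is not None:
        title = form_def.get("Name")
    title = title or form_id

    # Context: override > in-file alias > error
    context = dialect.context_override
    if context is None:
        context = _find_context_alias(study, mdv, form_def, dialect.context_alias)
    if not context:
        raise OdmFormatError(
            f"{name}: no documentation context (no context map entry and no "
            f"Alias with Context={dialect.context_alias!r})"
        )

    # Item order: FormDef -> ItemGroupRef -> ItemGroupDef -> ItemRef when
    # present, else MetaDataVersion document order of ItemDef.
    ordered_oids: list[str] = []
    if form_def is not None:
        for ig_ref in _find_all_local(form_def, "ItemGroupRef"):
            ig = item_group_defs.get(ig_ref.get("ItemGroupOID"))
            if ig is None:
                continue
            for item_ref in _find_all_local(ig, "ItemRef"):
                oid = item_ref.get("ItemOID")
                if oid in item_defs:
                    ordered_oids.append(oid)
    if not ordered_oids:
        ordered_oids = list(item_defs)

    items: list[AnnotatedItem] = []
    for oid in ordered_oids:
        items.append(_parse_item(item_defs[oid], name, dialect, report))
    if not items:
        report.add("warning", name, "", "form has no item definitions")

    return FormDocument(form_id=form_id, title=title, context=context, items=items)


def _find_context_alias(
    study: ET.Element,
    mdv: ET.Element,
    form_def: ET.Element | None,
    context_alias: str,
) -> str | None:
    scopes: list[ET.Element] = []
    protocol = next(iter(_find_all_local(mdv, "Protocol")), None)
    if protocol is not None:
        scopes.append(protocol)
    scopes.append(mdv)
    if form_def is not None:
        scopes.append(form_def)
    for scope in scopes:
        for alias in _find_all_local(scope, "Alias"):
            if alias.get("Context") == context_alias:
                return alias.get("Name")
    return None


def _parse_item(
    item_def: ET.Element, file: str, dialect: DialectConfig, report: ParseReport
) -> AnnotatedItem:
    oid = item_def.get("OID") or ""
    name = item_def.get("Name") or oid
    raw_dt = item_def.get("DataType") or "text"
    datatype = _ODM_DATATYPE_ALIASES.get(raw_dt, raw_dt)
    if _find_all_local(item_def, "CodeListRef"):
        datatype = "codelist"
    elif datatype not in DATATYPES:
        report.add(
            "warning", file, oid, f"unknown ODM DataType {raw_dt!r} mapped to text"
        )
        datatype = "text"

    question = ""
    q = next(iter(_find_all_local(item_def, "Question")), None)
    if q is not None:
        tt = next(iter(_find_all_local(q, "TranslatedText")), None)
        if tt is not None and tt.text:
            question = tt.text

    cuis: set[str] = set()
    invalid = False
    for alias in _find_all_local(item_def, "Alias"):
        if alias.get("Context") not in dialect.alias_contexts:
            continue
        raw = alias.get("Name") or ""
        try:
            cuis.update(parse_concept(raw).cuis)
        except ConceptError as exc:
            invalid = True
            report.add("warning", file, oid, f"invalid UMLS annotation: {exc}")
    code = ConceptCode(frozenset(cuis)) if cuis and not invalid else None
    if cuis and invalid:
        report.add(
            "warning", file, oid, "item left unannotated due to invalid annotation"
        )

    excluded = "none"
    for alias in _find_all_local(item_def, "Alias"):
        if alias.get("Context") == "ExclusionReason":
            reason = alias.get("Name") or "none"
            if reason in EXCLUSION_REASONS:
                excluded = reason

    return AnnotatedItem(
        item_id=oid,
        name=name,
        question=question,
        datatype=datatype,
        code=code,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Writing

#: Fixed creation stamp: outputs must be byte-identical under fixed inputs.
_CREATION_DATETIME = "1970-01-01T00:00:00"


def write_odm(form: FormDocument, dest: str | Path | IO) -> None:
    """Serialize a form so that ``read_odm(write_odm(f)) == f`` field-by-field."""
    ET.register_namespace("", ODM_NS)
    root = ET.Element(
        _tag("ODM"),
        {
            "FileOID": f"ODM.{form.form_id}",
            "FileType": "Snapshot",
            "ODMVersion": "1.3.2",
            "CreationDateTime": _CREATION_DATETIME,
        },
    )
    study = ET.SubElement(root, _tag("Study"), {"OID": f"S.{form.form_id}"})
    gv = ET.SubElement(study, _tag("GlobalVariables"))
    ET.SubElement(gv, _tag("StudyName")).text = form.title
    ET.SubElement(gv, _tag("StudyDescription")).text = form.title
    ET.SubElement(gv, _tag("ProtocolName")).text = form.form_id
    mdv = ET.SubElement(
        study, _tag("MetaDataVersion"), {"OID": "MDV.1", "Name": form.title}
    )
    protocol = ET.SubElement(mdv, _tag("Protocol"))
    ET.SubElement(
        protocol,
        _tag("Alias"),
        {"Context": "DocumentationContext", "Name": form.context},
    )
    form_def = ET.SubElement(
        mdv,
        _tag("FormDef"),
        {"OID": form.form_id, "Name": form.title, "Repeating": "No"},
    )
    ET.SubElement(
        form_def, _tag("ItemGroupRef"), {"ItemGroupOID": "IG.1", "Mandatory": "No"}
    )
    ig = ET.SubElement(
        mdv, _tag("ItemGroupDef"), {"OID": "IG.1", "Name": "Items", "Repeating": "No"}
    )
    codelist_needed = False
    for item in form.items:
        ET.SubElement(
            ig, _tag("ItemRef"), {"ItemOID": item.item_id, "Mandatory": "No"}
        )
    for item in form.items:
        odm_dt = "text" if item.datatype == "codelist" else item.datatype
        item_def = ET.SubElement(
            mdv,
            _tag("ItemDef"),
            {"OID": item.item_id, "Name": item.name, "DataType": odm_dt},
        )
        if item.question:
            q = ET.SubElement(item_def, _tag("Question"))
            tt = ET.SubElement(q, _tag("TranslatedText"), {XML_LANG: "en"})
            tt.text = item.question
        if item.datatype == "codelist":
            ET.SubElement(item_def, _tag("CodeListRef"), {"CodeListOID": "CL.1"})
            codelist_needed = True
        if item.code is not None:
            # Single whitespace-separated alias for postcoordinated codes.
            ET.SubElement(
                item_def, _tag("Alias"), {"Context": "UMLS", "Name": item.code.key}
            )
        if item.excluded != "none":
            ET.SubElement(
                item_def,
                _tag("Alias"),
                {"Context": "ExclusionReason", "Name": item.excluded},
            )
    if codelist_needed:
        code_list = ET.SubElement(
            mdv,
            _tag("CodeList"),
            {"OID": "CL.1", "Name": "Unspecified", "DataType": "text"},
        )
        ET.SubElement(code_list, _tag("EnumeratedItem"), {"CodedValue": "1"})

    ET.indent(root)
    tree = ET.ElementTree(root)
    if isinstance(dest, (str, Path)):
        tree.write(dest, encoding="utf-8", xml_declaration=True)
    else:
        tree.write(dest, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# Corpus reading


def load_context_map(path: str | Path) -> dict[str, dict]:
    """Load a sidecar corpus config (YAML/JSON): list of
    ``{path, context, form_id}`` entries, or a flat ``{path: context}`` map.
    """
    import yaml

    with open(path, encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    result: dict[str, dict] = {}
    if isinstance(data, dict):
        entries = data.get("forms", data)
        if isinstance(entries, dict):
            for key, value in entries.items():
                result[str(key)] = (
                    dict(value) if isinstance(value, dict) else {"context": value}
                )
            return result
        data = entries
    for entry in data or []:
        entry = dict(entry)
        result[str(entry.pop("path"))] = entry
    return result


def _lookup_context_entry(
    context_map: Mapping[str, object] | None, path: Path
) -> dict:
    if not context_map:
        return {}
    for key in (str(path), path.name):
        if key in context_map:
            value = context_map[key]
            return dict(value) if isinstance(value, dict) else {"context": value}
    return {}


class Corpus(list):
    """A list of :class:`FormDocument` with an attached :class:`ParseReport`."""

    def __init__(self, forms: Iterable[FormDocument], report: ParseReport):
        super().__init__(forms)
        self.report = report


def read_corpus(
    paths: Sequence[str | Path],
    context_map: Mapping[str, object] | None = None,
    default_context: str | None = None,
    dialect: DialectConfig | None = None,
    keep_going: bool = False,
) -> Corpus:
    """Read many ODM files into one corpus with aggregated diagnostics.

    ``context_map`` maps a path (full or basename) to a context label or to
    ``{"context": ..., "form_id": ...}``.  Duplicate form ids across files
    are made unique by deterministic suffixing (``#2``, ``#3``, ...).  A
    file-level parse error aborts the batch unless ``keep_going`` is set, in
    which case it becomes an error record in the report.
    """
    base_dialect = dialect or DialectConfig()
    report = ParseReport()
    forms: list[FormDocument] = []
    if not paths:
        report.add("warning", "", "", "empty path list: corpus is empty")
        return Corpus(forms, report)

    seen_ids: dict[str, int] = {}
    for raw_path in paths:
        path = Path(raw_path)
        entry = _lookup_context_entry(context_map, path)
        context = entry.get("context") or default_context
        file_dialect = DialectConfig(
            alias_contexts=base_dialect.alias_contexts,
            context_alias=base_dialect.context_alias,
            context_override=context or base_dialect.context_override,
        )
        try:
            form = read_odm(path, dialect=file_dialect, report=report)
        except (OdmError, OSError) as exc:
            if not keep_going:
                raise
            report.add("error", str(path), "", str(exc))
            continue
        if entry.get("form_id"):
            form.form_id = str(entry["form_id"])
        count = seen_ids.get(form.form_id, 0) + 1
        seen_ids[form.form_id] = count
        if count > 1:
            new_id = f"{form.form_id}#{count}"
            report.add(
                "warning",
                str(path),
                "",
                f"duplicate form_id {form.form_id!r} renamed to {new_id!r}",
            )
            form.form_id = new_id
        forms.append(form)
    return Corpus(forms, report)
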