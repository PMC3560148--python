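"""Parse and write SRA-format XML metadata object sets.

The Sequence Read Archive describes every submission with five metadata
objects — submission, study, sample, experiment and run — each carried in an
XML "object set" document (SUBMISSION_SET, STUDY_SET, ...).  This module maps
those documents onto flat, typed records suitable for a relational store.

Parsing is deliberately faithful: field values are captured verbatim, nothing
is case-folded, trimmed beyond XML whitespace handling, or semantically
recoded.  Absent or empty elements become ``None``.  Children that may repeat
(attribute tags, URL links, platform parameters) are flattened into a single
delimited text field via :func:`flatten_multivalue`.

A writer is provided so that fixture generators and round-trip tests can emit
the same dialect the parser consumes.  Two fields have no home in the official
object schemas and are carried as extra XML attributes of the object element:
``submission_accession`` (on STUDY/SAMPLE/EXPERIMENT/RUN) and ``updated_date``
(on RUN).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, fields as dc_fields
from typing import Optional

from lxml import etree

from .errors import KindMismatchError, RecordError, SraXmlError

logger = logging.getLogger(__name__)

KINDS = ("submission", "study", "sample", "experiment", "run")

#: accession shape per entity kind: archive letter (S=NCBI, E=EBI, D=DDBJ)
#: then R, then the object-kind letter, then digits.
ACCESSION_PATTERNS = {
    "submission": re.compile(r"^[SED]RA\d+$"),
    "study": re.compile(r"^[SED]RP\d+$"),
    "sample": re.compile(r"^[SED]RS\d+$"),
    "experiment": re.compile(r"^[SED]RX\d+$"),
    "run": re.compile(r"^[SED]RR\d+$"),
}

ANY_ACCESSION = re.compile(r"^[SED]R[APSXR]\d+$")

MULTIVALUE_DELIMITER = " || "
_ESCAPED_BARS = "¦¦"  # "¦¦"


def flatten_multivalue(items) -> Optional[str]:
    """Flatten (tag, value) pairs into a single delimited text field.

    Pairs are joined as ``tag: value`` separated by ``" || "``, preserving
    document order.  An empty list flattens to ``None``.  Any literal ``||``
    inside a tag or value is escaped to ``¦¦`` so the delimiter remains
    unambiguous.
    """
    items = list(items)
    if not items:
        return None
    parts = []
    for tag, value in items:
        tag = "" if tag is None else str(tag).replace("||", _ESCAPED_BARS)
        value = "" if value is None else str(value).replace("||", _ESCAPED_BARS)
        parts.append(f"{tag}: {value}")
    return MULTIVALUE_DELIMITER.join(parts)


def split_multivalue(text: Optional[str]):
    """Inverse of :func:`flatten_multivalue` for escape-free inputs."""
    if text is None:
        return []
    pairs = []
    for part in text.split(MULTIVALUE_DELIMITER):
        tag, sep, value = part.partition(": ")
        if not sep:
            tag, value = part, ""
        pairs.append((tag.replace(_ESCAPED_BARS, "||"), value.replace(_ESCAPED_BARS, "||")))
    return pairs


# ---------------------------------------------------------------------------
# record types

@dataclass
class SubmissionRecord:
    submission_accession: str
    submission_alias: Optional[str] = None
    center_name: Optional[str] = None
    broker_name: Optional[str] = None
    lab_name: Optional[str] = None
    submission_date: Optional[str] = None
    submission_comment: Optional[str] = None
    submission_attribute: Optional[str] = None


@dataclass
class StudyRecord:
    study_accession: str
    study_alias: Optional[str] = None
    study_title: Optional[str] = None
    study_type: Optional[str] = None
    study_abstract: Optional[str] = None
    center_name: Optional[str] = None
    center_project_name: Optional[str] = None
    study_description: Optional[str] = None
    study_url_link: Optional[str] = None
    study_attribute: Optional[str] = None
    submission_accession: Optional[str] = None


@dataclass
class SampleRecord:
    sample_accession: str
    sample_alias: Optional[str] = None
    taxon_id: Optional[int] = None
    scientific_name: Optional[str] = None
    common_name: Optional[str] = None
    description: Optional[str] = None
    sample_attribute: Optional[str] = None
    submission_accession: Optional[str] = None


@dataclass
class ExperimentRecord:
    experiment_accession: str
    experiment_alias: Optional[str] = None
    title: Optional[str] = None
    study_accession: Optional[str] = None
    sample_accession: Optional[str] = None
    design_description: Optional[str] = None
    library_name: Optional[str] = None
    library_strategy: Optional[str] = None
    library_source: Optional[str] = None
    library_selection: Optional[str] = None
    library_layout: Optional[str] = None
    library_construction_protocol: Optional[str] = None
    spot_length: Optional[int] = None
    platform: Optional[str] = None
    instrument_model: Optional[str] = None
    platform_parameters: Optional[str] = None
    experiment_attribute: Optional[str] = None
    submission_accession: Optional[str] = None


@dataclass
class RunRecord:
    run_accession: str
    run_alias: Optional[str] = None
    run_date: Optional[str] = None
    updated_date: Optional[str] = None
    spots: Optional[int] = None
    bases: Optional[int] = None
    run_center: Optional[str] = None
    experiment_accession: Optional[str] = None
    run_attribute: Optional[str] = None
    submission_accession: Optional[str] = None


RECORD_TYPES = {
    "submission": SubmissionRecord,
    "study": StudyRecord,
    "sample": SampleRecord,
    "experiment": ExperimentRecord,
    "run": RunRecord,
}

KIND_OF_RECORD = {cls: kind for kind, cls in RECORD_TYPES.items()}

SET_ELEMENTS = {
    "submission": "SUBMISSION_SET",
    "study": "STUDY_SET",
    "sample": "SAMPLE_SET",
    "experiment": "EXPERIMENT_SET",
    "run": "RUN_SET",
}

OBJECT_ELEMENTS = {
    "submission": "SUBMISSION",
    "study": "STUDY",
    "sample": "SAMPLE",
    "experiment": "EXPERIMENT",
    "run": "RUN",
}


def record_kind(record) -> str:
    try:
        return KIND_OF_RECORD[type(record)]
    except KeyError:
        raise SraXmlError(f"not an SRA entity record: {record!r}")


def accession_of(record) -> str:
    return getattr(record, f"{record_kind(record)}_accession")


def validate_accession(kind: str, accession: Optional[str]) -> bool:
    return accession is not None and bool(ACCESSION_PATTERNS[kind].match(accession))


# ---------------------------------------------------------------------------
# parsing helpers

def _text(elem) -> Optional[str]:
    """Element text, with empty/whitespace-only content treated as null."""
    if elem is None or elem.text is None:
        return None
    return elem.text if elem.text.strip() else None


def _find_text(parent, path) -> Optional[str]:
    return _text(parent.find(path)) if parent is not None else None


def _attr(elem, name) -> Optional[str]:
    if elem is None:
        return None
    value = elem.get(name)
    return value if value not in (None, "") else None


def _int_or_none(value, what) -> Optional[int]:
    if value is None:
        return None
    try:
        return int(value)
    except ValueError:
        raise SraXmlError(f"non-integer value {value!r} for {what}")


def _attributes_block(obj, block, item):
    """Collect TAG/VALUE pairs from e.g. RUN_ATTRIBUTES/RUN_ATTRIBUTE."""
    pairs = []
    holder = obj.find(block)
    if holder is None:
        return None
    for child in holder.findall(item):
        tag = _find_text(child, "TAG")
        value = _find_text(child, "VALUE")
        pairs.append((tag or "", value or ""))
    return flatten_multivalue(pairs)


def _parse_submission(obj) -> SubmissionRecord:
    return SubmissionRecord(
        submission_accession=_attr(obj, "accession"),
        submission_alias=_attr(obj, "alias"),
        center_name=_attr(obj, "center_name"),
        broker_name=_attr(obj, "broker_name"),
        lab_name=_attr(obj, "lab_name"),
        submission_date=_attr(obj, "submission_date"),
        submission_comment=_attr(obj, "submission_comment"),
        submission_attribute=_attributes_block(
            obj, "SUBMISSION_ATTRIBUTES", "SUBMISSION_ATTRIBUTE"),
    )


def _parse_study(obj) -> StudyRecord:
    descriptor = obj.find("DESCRIPTOR")
    study_type = None
    if descriptor is not None:
        type_elem = descriptor.find("STUDY_TYPE")
        study_type = _attr(type_elem, "existing_study_type")
    links = []
    links_holder = obj.find("STUDY_LINKS")
    if links_holder is not None:
        for link in links_holder.findall("STUDY_LINK/URL_LINK"):
            links.append((_find_text(link, "LABEL") or "", _find_text(link, "URL") or ""))
    return StudyRecord(
        study_accession=_attr(obj, "accession"),
        study_alias=_attr(obj, "alias"),
        study_title=_find_text(descriptor, "STUDY_TITLE"),
        study_type=study_type,
        study_abstract=_find_text(descriptor, "STUDY_ABSTRACT"),
        center_name=_attr(obj, "center_name"),
        center_project_name=_find_text(descriptor, "CENTER_PROJECT_NAME"),
        study_description=_find_text(descriptor, "STUDY_DESCRIPTION"),
        study_url_link=flatten_multivalue(links) if links else None,
        study_attribute=_attributes_block(obj, "STUDY_ATTRIBUTES", "STUDY_ATTRIBUTE"),
        submission_accession=_attr(obj, "submission_accession"),
    )


def _parse_sample(obj) -> SampleRecord:
    name = obj.find("SAMPLE_NAME")
    return SampleRecord(
        sample_accession=_attr(obj, "accession"),
        sample_alias=_attr(obj, "alias"),
        taxon_id=_int_or_none(_find_text(name, "TAXON_ID"), "TAXON_ID"),
        scientific_name=_find_text(name, "SCIENTIFIC_NAME"),
        common_name=_find_text(name, "COMMON_NAME"),
        description=_find_text(obj, "DESCRIPTION"),
        sample_attribute=_attributes_block(obj, "SAMPLE_ATTRIBUTES", "SAMPLE_ATTRIBUTE"),
        submission_accession=_attr(obj, "submission_accession"),
    )


def _parse_experiment(obj) -> ExperimentRecord:
    design = obj.find("DESIGN")
    lib = design.find("LIBRARY_DESCRIPTOR") if design is not None else None
    layout = None
    if lib is not None:
        layout_elem = lib.find("LIBRARY_LAYOUT")
        if layout_elem is not None and len(layout_elem):
            layout = layout_elem[0].tag
    platform = None
    instrument_model = None
    platform_params = []
    platform_elem = obj.find("PLATFORM")
    if platform_elem is not None and len(platform_elem):
        inner = platform_elem[0]
        platform = inner.tag
        for child in inner:
            if child.tag == "INSTRUMENT_MODEL":
                instrument_model = _text(child)
            else:
                platform_params.append((child.tag, _text(child) or ""))
    spot_length = None
    if design is not None:
        spot_length = _find_text(design, "SPOT_DESCRIPTOR/SPOT_DECODE_SPEC/SPOT_LENGTH")
    study_ref = obj.find("STUDY_REF")
    sample_ref = design.find("SAMPLE_DESCRIPTOR") if design is not None else None
    return ExperimentRecord(
        experiment_accession=_attr(obj, "accession"),
        experiment_alias=_attr(obj, "alias"),
        title=_find_text(obj, "TITLE"),
        study_accession=_attr(study_ref, "accession"),
        sample_accession=_attr(sample_ref, "accession"),
        design_description=_find_text(design, "DESIGN_DESCRIPTION"),
        library_name=_find_text(lib, "LIBRARY_NAME"),
        library_strategy=_find_text(lib, "LIBRARY_STRATEGY"),
        library_source=_find_text(lib, "LIBRARY_SOURCE"),
        library_selection=_find_text(lib, "LIBRARY_SELECTION"),
        library_layout=layout,
        library_construction_protocol=_find_text(lib, "LIBRARY_CONSTRUCTION_PROTOCOL"),
        spot_length=_int_or_none(spot_length, "SPOT_LENGTH"),
        platform=platform,
        instrument_model=instrument_model,
        platform_parameters=flatten_multivalue(platform_params) if platform_params else None,
        experiment_attribute=_attributes_block(
            obj, "EXPERIMENT_ATTRIBUTES", "EXPERIMENT_ATTRIBUTE"),
        submission_accession=_attr(obj, "submission_accession"),
    )


def _parse_run(obj) -> RunRecord:
    exp_ref = obj.find("EXPERIMENT_REF")
    return RunRecord(
        run_accession=_attr(obj, "accession"),
        run_alias=_attr(obj, "alias"),
        run_date=_attr(obj, "run_date"),
        updated_date=_attr(obj, "updated_date"),
        spots=_int_or_none(_attr(obj, "total_spots"), "total_spots"),
        bases=_int_or_none(_attr(obj, "total_bases"), "total_bases"),
        run_center=_attr(obj, "run_center"),
        experiment_accession=_attr(exp_ref, "accession"),
        run_attribute=_attributes_block(obj, "RUN_ATTRIBUTES", "RUN_ATTRIBUTE"),
        submission_accession=_attr(obj, "submission_accession"),
    )


_PARSERS = {
    "submission": _parse_submission,
    "study": _parse_study,
    "sample": _parse_sample,
    "experiment": _parse_experiment,
    "run": _parse_run,
}

_KNOWN_TOP_LEVEL = {
    "submission": {"SUBMISSION_ATTRIBUTES"},
    "study": {"DESCRIPTOR", "STUDY_LINKS", "STUDY_ATTRIBUTES"},
    "sample": {"SAMPLE_NAME", "DESCRIPTION", "SAMPLE_ATTRIBUTES"},
    "experiment": {"TITLE", "STUDY_REF", "DESIGN", "PLATFORM", "EXPERIMENT_ATTRIBUTES"},
    "run": {"EXPERIMENT_REF", "RUN_ATTRIBUTES"},
}


def parse_object_set(xml_document, kind: str):
    """Parse one SRA object-set document into a list of typed records.

    ``kind`` names the expected entity ("run", "study", ...).  A document
    whose root element belongs to a different kind raises
    :class:`KindMismatchError`; malformed XML raises :class:`SraXmlError`
    naming the offending line; objects lacking an accession attribute raise
    :class:`RecordError` listing their aliases.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown entity kind {kind!r}; expected one of {KINDS}")
    if isinstance(xml_document, str):
        xml_document = xml_document.encode("utf-8")
    try:
        root = etree.fromstring(xml_document)
    except etree.XMLSyntaxError as exc:
        raise SraXmlError(f"malformed XML at line {exc.lineno}: {exc.msg}") from exc
    expected = SET_ELEMENTS[kind]
    if root.tag != expected:
        raise KindMismatchError(
            f"expected root element {expected} for kind {kind!r}, found {root.tag}")
    parser = _PARSERS[kind]
    records, missing = [], []
    for obj in root.findall(OBJECT_ELEMENTS[kind]):
        for child in obj:
            if child.tag not in _KNOWN_TOP_LEVEL[kind]:
                logger.debug("ignoring unmapped element <%s> in %s", child.tag, kind)
        record = parser(obj)
        if accession_of(record) is None:
            missing.append(_attr(obj, "alias") or "<no alias>")
            continue
        records.append(record)
    if missing:
        raise RecordError(
            f"{len(missing)} {kind} object(s) lack an accession attribute "
            f"(aliases: {', '.join(missing)})",
            aliases=missing)
    return records


# ---------------------------------------------------------------------------
# writer

def _set_attr(elem, name, value):
    if value is not None:
        elem.set(name, str(value))


def _sub_text(parent, tag, value):
    if value is not None:
        etree.SubElement(parent, tag).text = str(value)
    return None


def _attributes_elem(parent, block, item, delimited):
    pairs = split_multivalue(delimited)
    if not pairs:
        return
    holder = etree.SubElement(parent, block)
    for tag, value in pairs:
        attr = etree.SubElement(holder, item)
        etree.SubElement(attr, "TAG").text = tag
        etree.SubElement(attr, "VALUE").text = value


def _write_submission(parent, r: SubmissionRecord):
    obj = etree.SubElement(parent, "SUBMISSION")
    _set_attr(obj, "accession", r.submission_accession)
    _set_attr(obj, "alias", r.submission_alias)
    _set_attr(obj, "center_name", r.center_name)
    _set_attr(obj, "broker_name", r.broker_name)
    _set_attr(obj, "lab_name", r.lab_name)
    _set_attr(obj, "submission_date", r.submission_date)
    _set_attr(obj, "submission_comment", r.submission_comment)
    _attributes_elem(obj, "SUBMISSION_ATTRIBUTES", "SUBMISSION_ATTRIBUTE",
                     r.submission_attribute)


def _write_study(parent, r: StudyRecord):
    obj = etree.SubElement(parent, "STUDY")
    _set_attr(obj, "accession", r.study_accession)
    _set_attr(obj, "alias", r.study_alias)
    _set_attr(obj, "center_name", r.center_name)
    _set_attr(obj, "submission_accession", r.submission_accession)
    if any(v is not None for v in (r.study_title, r.study_type, r.study_abstract,
                                   r.center_project_name, r.study_description)):
        descriptor = etree.SubElement(obj, "DESCRIPTOR")
        _sub_text(descriptor, "STUDY_TITLE", r.study_title)
        if r.study_type is not None:
            etree.SubElement(descriptor, "STUDY_TYPE").set(
                "existing_study_type", r.study_type)
        _sub_text(descriptor, "STUDY_ABSTRACT", r.study_abstract)
        _sub_text(descriptor, "CENTER_PROJECT_NAME", r.center_project_name)
        _sub_text(descriptor, "STUDY_DESCRIPTION", r.study_description)
    links = split_multivalue(r.study_url_link)
    if links:
        holder = etree.SubElement(obj, "STUDY_LINKS")
        for label, url in links:
            link = etree.SubElement(etree.SubElement(holder, "STUDY_LINK"), "URL_LINK")
            etree.SubElement(link, "LABEL").text = label
            etree.SubElement(link, "URL").text = url
    _attributes_elem(obj, "STUDY_ATTRIBUTES", "STUDY_ATTRIBUTE", r.study_attribute)


def _write_sample(parent, r: SampleRecord):
    obj = etree.SubElement(parent, "SAMPLE")
    _set_attr(obj, "accession", r.sample_accession)
    _set_attr(obj, "alias", r.sample_alias)
    _set_attr(obj, "submission_accession", r.submission_accession)
    if any(v is not None for v in (r.taxon_id, r.scientific_name, r.common_name)):
        name = etree.SubElement(obj, "SAMPLE_NAME")
        _sub_text(name, "TAXON_ID", r.taxon_id)
        _sub_text(name, "SCIENTIFIC_NAME", r.scientific_name)
        _sub_text(name, "COMMON_NAME", r.common_name)
    _sub_text(obj, "DESCRIPTION", r.description)
    _attributes_elem(obj, "SAMPLE_ATTRIBUTES", "SAMPLE_ATTRIBUTE", r.sample_attribute)


def _write_experiment(parent, r: ExperimentRecord):
    obj = etree.SubElement(parent, "EXPERIMENT")
    _set_attr(obj, "accession", r.experiment_accession)
    _set_attr(obj, "alias", r.experiment_alias)
    _set_attr(obj, "submission_accession", r.submission_accession)
    _sub_text(obj, "TITLE", r.title)
    if r.study_accession is not None:
        etree.SubElement(obj, "STUDY_REF").set("accession", r.study_accession)
    design = etree.SubElement(obj, "DESIGN")
    _sub_text(design, "DESIGN_DESCRIPTION", r.design_description)
    if r.sample_accession is not None:
        etree.SubElement(design, "SAMPLE_DESCRIPTOR").set("accession", r.sample_accession)
    lib = etree.SubElement(design, "LIBRARY_DESCRIPTOR")
    _sub_text(lib, "LIBRARY_NAME", r.library_name)
    _sub_text(lib, "LIBRARY_STRATEGY", r.library_strategy)
    _sub_text(lib, "LIBRARY_SOURCE", r.library_source)
    _sub_text(lib, "LIBRARY_SELECTION", r.library_selection)
    if r.library_layout is not None:
        etree.SubElement(etree.SubElement(lib, "LIBRARY_LAYOUT"), r.library_layout)
    _sub_text(lib, "LIBRARY_CONSTRUCTION_PROTOCOL", r.library_construction_protocol)
    if r.spot_length is not None:
        spot = etree.SubElement(etree.SubElement(design, "SPOT_DESCRIPTOR"),
                                "SPOT_DECODE_SPEC")
        _sub_text(spot, "SPOT_LENGTH", r.spot_length)
    if r.platform is not None:
        inner = etree.SubElement(etree.SubElement(obj, "PLATFORM"), r.platform)
        _sub_text(inner, "INSTRUMENT_MODEL", r.instrument_model)
        for tag, value in split_multivalue(r.platform_parameters):
            etree.SubElement(inner, tag).text = value
    _attributes_elem(obj, "EXPERIMENT_ATTRIBUTES", "EXPERIMENT_ATTRIBUTE",
                     r.experiment_attribute)


def _write_run(parent, r: RunRecord):
    obj = etree.SubElement(parent, "RUN")
    _set_attr(obj, "accession", r.run_accession)
    _set_attr(obj, "alias", r.run_alias)
    _set_attr(obj, "run_date", r.run_date)
    _set_attr(obj, "updated_date", r.updated_date)
    _set_attr(obj, "total_spots", r.spots)
    _set_attr(obj, "total_bases", r.bases)
    _set_attr(obj, "run_center", r.run_center)
    _set_attr(obj, "submission_accession", r.submission_accession)
    if r.experiment_accession is not None:
        etree.SubElement(obj, "EXPERIMENT_REF").set("accession", r.experiment_accession)
    _attributes_elem(obj, "RUN_ATTRIBUTES", "RUN_ATTRIBUTE", r.run_attribute)


_WRITERS = {
    "submission": _write_submission,
    "study": _write_study,
    "sample": _write_sample,
    "experiment": _write_experiment,
    "run": _write_run,
}


def write_object_set(records, kind: Optional[str] = None) -> str:
    """Serialize records of one kind to an SRA object-set XML document.

    The output re-parses (via :func:`parse_object_set`) to records equal
    field-by-field.  ``kind`` is inferred from the records and only needed
    for an empty list.
    """
    records = list(records)
    kinds = {record_kind(r) for r in records}
    if len(kinds) > 1:
        raise SraXmlError(f"mixed record kinds in one object set: {sorted(kinds)}")
    if kinds:
        inferred = kinds.pop()
        if kind is not None and kind != inferred:
            raise KindMismatchError(f"records are {inferred!r}, not {kind!r}")
        kind = inferred
    elif kind is None:
        raise ValueError("kind is required to write an empty object set")
    for r in records:
        acc = accession_of(r)
        if not validate_accession(kind, acc):
            raise SraXmlError(f"invalid {kind} accession: {acc!r}")
    root = etree.Element(SET_ELEMENTS[kind])
    writer = _WRITERS[kind]
    for r in records:
        writer(root, r)
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")


def record_fields(kind: str):
    """Ordered field names of the record type for ``kind``."""
    return [f.name for f in dc_fields(RECORD_TYPES[kind])]
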