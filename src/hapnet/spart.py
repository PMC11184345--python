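"""SPART and SPART-XML species-partition files.

A SPART document carries one or more alternative *spartitions* — named
partitions of the same set of individuals into subsets (candidate
species).  The matricial dialect is the keyword/assignment text format;
the XML dialect encodes the same content as nested elements.  Optional
fields (dates, scores, remarks) are preserved opaquely and re-emitted on
write, but only the assignments drive any computation here.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import CoverageError, ParseError, PartitionLookupError


@dataclass
class Spartition:
    """One named partition: individual -> subset label."""

    name: str
    assignment: dict[str, str]
    subsets: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen = []
        for subset in self.assignment.values():
            if subset not in seen:
                seen.append(subset)
        if not self.subsets:
            self.subsets = seen
        elif set(self.subsets) != set(seen):
            raise CoverageError(
                f"spartition {self.name!r}: subset list does not match assignments"
            )

    def members(self, subset: str) -> list[str]:
        return [i for i, s in self.assignment.items() if s == subset]


@dataclass
class SpartDocument:
    project: Optional[str]
    spartitions: list[Spartition]
    individuals: list[str]
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.spartitions:
            raise ParseError("SPART document contains no spartition")
        expected = set(self.individuals)
        for sp in self.spartitions:
            got = set(sp.assignment)
            if got != expected:
                missing = sorted(expected - got)
                extra = sorted(got - expected)
                raise CoverageError(
                    f"spartition {sp.name!r} does not cover the document's "
                    f"individuals (missing: {missing}, extra: {extra})"
                )


def select_partition(doc: SpartDocument, which: Union[str, int]) -> Spartition:
    """Pick a spartition by 0-based index or by name."""
    if isinstance(which, int):
        if not 0 <= which < len(doc.spartitions):
            raise PartitionLookupError(
                f"spartition index {which} out of range 0..{len(doc.spartitions) - 1}"
            )
        return doc.spartitions[which]
    for sp in doc.spartitions:
        if sp.name == which:
            return sp
    names = ", ".join(sp.name for sp in doc.spartitions)
    raise PartitionLookupError(f"no spartition named {which!r}; available: {names}")


# -- matricial dialect -------------------------------------------------------

_KNOWN_KEYS = {"project_name", "n_spartitions", "n_subsets", "individual_assignment"}


def _parse_matricial(text: str) -> SpartDocument:
    # Join logical statements: each ends with ';'
    body = re.sub(r"^\s*begin\s+spart\s*;", "", text.strip(), flags=re.I)
    body = re.sub(r"end\s*;\s*$", "", body, flags=re.I)
    statements = [s.strip() for s in body.split(";") if s.strip()]
    project = None
    names: list[str] = []
    extras: dict[str, str] = {}
    assignments: list[tuple[str, list[str]]] = []
    for stmt in statements:
        if "=" not in stmt:
            raise ParseError(f"unparseable SPART statement: {stmt!r}")
        key, value = (p.strip() for p in stmt.split("=", 1))
        lkey = key.lower()
        if lkey == "project_name":
            project = value
        elif lkey == "n_spartitions":
            if ":" in value:
                _, namepart = value.split(":", 1)
                names = [n.strip() for n in namepart.split("/")]
            else:
                names = []
        elif lkey == "n_subsets":
            pass  # implied by the assignments; validated below
        elif lkey == "individual_assignment":
            for row in value.splitlines():
                row = row.strip().rstrip(",")
                if not row:
                    continue
                if ":" not in row:
                    raise ParseError(f"unparseable assignment row: {row!r}")
                ind, codes = (p.strip() for p in row.split(":", 1))
                assignments.append((ind, [c.strip() for c in codes.split("/")]))
        else:
            extras[key] = value
    if not assignments:
        raise ParseError("SPART file has no individual_assignment block")
    width = len(assignments[0][1])
    for ind, codes in assignments:
        if len(codes) != width:
            raise CoverageError(
                f"individual {ind!r} is assigned in {len(codes)} spartitions, "
                f"expected {width}"
            )
    if not names:
        names = [f"spartition_{i + 1}" for i in range(width)]
    if len(names) != width:
        raise ParseError(
            f"n_spartitions declares {len(names)} names but assignments have "
            f"{width} columns"
        )
    individuals = [ind for ind, _ in assignments]
    spartitions = [
        Spartition(
            name=names[i],
            assignment={ind: codes[i] for ind, codes in assignments},
        )
        for i in range(width)
    ]
    return SpartDocument(project, spartitions, individuals, extras)


def _write_matricial(doc: SpartDocument) -> str:
    lines = ["begin spart;"]
    if doc.project is not None:
        lines.append(f"project_name = {doc.project};")
    for key, value in doc.extras.items():
        lines.append(f"{key} = {value};")
    names = " / ".join(sp.name for sp in doc.spartitions)
    lines.append(f"n_spartitions = {len(doc.spartitions)} : {names};")
    lines.append(
        "n_subsets = " + " / ".join(str(len(sp.subsets)) for sp in doc.spartitions) + ";"
    )
    lines.append("individual_assignment =")
    for ind in doc.individuals:
        codes = " / ".join(sp.assignment[ind] for sp in doc.spartitions)
        lines.append(f"{ind} : {codes}")
    lines.append(";")
    lines.append("end;")
    return "\n".join(lines) + "\n"


# -- XML dialect -------------------------------------------------------------

def _parse_xml(text: str) -> SpartDocument:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"cannot parse SPART-XML: {exc}") from exc
    project = None
    proj_el = root.find("project_name")
    if proj_el is not None:
        project = (proj_el.text or "").strip() or None
    extras = {}
    for el in root.findall("extra"):
        extras[el.get("key", "")] = el.text or ""
    ind_parent = root.find("individuals")
    if ind_parent is None:
        raise ParseError("SPART-XML lacks an <individuals> element")
    individuals = [el.get("id") for el in ind_parent.findall("individual")]
    if any(i is None for i in individuals):
        raise ParseError("<individual> element without id attribute")
    spartitions = []
    sp_parent = root.find("spartitions")
    if sp_parent is None:
        raise ParseError("SPART-XML lacks a <spartitions> element")
    for sp_el in sp_parent.findall("spartition"):
        name = sp_el.get("label") or f"spartition_{len(spartitions) + 1}"
        assignment: dict[str, str] = {}
        subsets: list[str] = []
        for sub_el in sp_el.findall("./subsets/subset"):
            label = sub_el.get("label")
            if label is None:
                raise ParseError(f"subset without label in spartition {name!r}")
            subsets.append(label)
            for ref_el in sub_el.findall("individual"):
                ref = ref_el.get("ref")
                if ref is None:
                    raise ParseError("subset member without ref attribute")
                assignment[ref] = label
        # keep document individual order in the assignment mapping
        ordered = {i: assignment[i] for i in individuals if i in assignment}
        ordered.update({i: s for i, s in assignment.items() if i not in ordered})
        spartitions.append(Spartition(name=name, assignment=ordered, subsets=subsets))
    return SpartDocument(project, spartitions, individuals, extras)


def _write_xml(doc: SpartDocument) -> str:
    root = ET.Element("spart")
    if doc.project is not None:
        ET.SubElement(root, "project_name").text = doc.project
    for key, value in doc.extras.items():
        el = ET.SubElement(root, "extra", key=key)
        el.text = value
    ind_parent = ET.SubElement(root, "individuals")
    for ind in doc.individuals:
        ET.SubElement(ind_parent, "individual", id=ind)
    sp_parent = ET.SubElement(root, "spartitions")
    for sp in doc.spartitions:
        sp_el = ET.SubElement(sp_parent, "spartition", label=sp.name)
        subs_el = ET.SubElement(sp_el, "subsets")
        for subset in sp.subsets:
            sub_el = ET.SubElement(subs_el, "subset", label=subset)
            for ind in doc.individuals:
                if sp.assignment[ind] == subset:
                    ET.SubElement(sub_el, "individual", ref=ind)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


# -- public API --------------------------------------------------------------

def read_spart(path) -> SpartDocument:
    """Read a SPART file; dialect detected by a leading ``<``."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith("<"):
        return _parse_xml(text)
    return _parse_matricial(text)


def write_spart(doc: SpartDocument, path, dialect: str = "spart") -> None:
    if dialect == "spart":
        out = _write_matricial(doc)
    elif dialect == "spart-xml":
        out = _write_xml(doc)
    else:
        raise ValueError(f"unknown SPART dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(out)
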