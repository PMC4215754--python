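"""KGML pathway model and I/O.

KGML (KEGG Markup Language) is the XML format KEGG ships alongside each
pathway map: a ``<pathway>`` root holding ``<entry>`` elements (nodes —
gene groups, compounds, linked maps, complexes) and ``<relation>`` elements
(edges, refined by ``<subtype>`` children).  This module provides plain
dataclasses for that model, a validating parser, a deterministic writer,
a single-pathway REST fetch, and a SIF-style edge-list export.

Metabolic ``<reaction>`` elements are outside the protein-interaction scope
of this package and are skipped with a logged warning.
"""

from __future__ import annotations

import copy
import logging
import urllib.error
import urllib.request
from dataclasses import dataclass, field

from lxml import etree

logger = logging.getLogger(__name__)

ENTRY_TYPES = {"gene", "compound", "map", "group", "ortholog", "enzyme", "other"}
RELATION_TYPES = {"PPrel", "ECrel", "GErel", "PCrel", "maplink"}

#: KGML controlled vocabulary for relation subtypes.  Unknown names are
#: preserved verbatim but flagged in the log.
SUBTYPE_NAMES = {
    "compound",
    "hidden compound",
    "activation",
    "inhibition",
    "expression",
    "repression",
    "indirect effect",
    "state change",
    "binding/association",
    "dissociation",
    "missing interaction",
    "phosphorylation",
    "dephosphorylation",
    "glycosylation",
    "ubiquitination",
    "methylation",
}

#: KEGG individual-download terms: per-pathway retrieval via the REST API is
#: permitted for academic use only; bulk download requires a KEGG license.
ACADEMIC_USE_NOTICE = (
    "KEGG REST retrieval is for individual, academic use only; "
    "bulk download and non-academic use require a KEGG FTP subscription "
    "(https://www.kegg.jp/kegg/legal.html)."
)

DEFAULT_REST_URL = "https://rest.kegg.jp/get/{org}{number}/kgml"


class KGMLError(Exception):
    """Base class for KGML model errors."""


class KGMLParseError(KGMLError):
    """Malformed XML; the message names the offending line when known."""


class KGMLValidationError(KGMLError):
    """Structurally well-formed document violating the pathway model."""


class PathwayUnavailableError(KGMLError):
    """The requested pathway does not exist in the remote database."""


class TransportError(KGMLError):
    """Network-level failure while fetching a pathway."""


@dataclass
class Graphics:
    """Visual attributes of an entry: centered box coordinates in pixels,
    top-left origin with y increasing downward (the KGML convention)."""

    label: str = ""
    x: int = 0
    y: int = 0
    width: int = 46
    height: int = 17
    shape: str = "rectangle"
    fgcolor: str = "#000000"
    bgcolor: str = "#FFFFFF"
    extra: dict = field(default_factory=dict)


@dataclass
class Subtype:
    """One ``<subtype>`` refinement of a relation.  For name ``compound``
    the value is the mediating compound's entry id."""

    name: str
    value: str = ""

    def key(self):
        return (self.name, self.value)


@dataclass
class PathwayRelation:
    """A directed pathway edge between two entry ids."""

    entry1: int
    entry2: int
    type: str
    subtypes: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def key(self):
        """Identity tuple used to collapse duplicate relations."""
        return (
            self.entry1,
            self.entry2,
            self.type,
            tuple(sorted(s.key() for s in self.subtypes)),
        )

    def has_subtype(self, name: str) -> bool:
        return any(s.name == name for s in self.subtypes)


@dataclass
class PathwayEntry:
    """A pathway node: a group of paralogous genes, a compound, a linked
    map, or a ``group`` container bundling component entries (a complex)."""

    id: int
    names: list
    type: str
    link: str = ""
    graphics: Graphics = field(default_factory=Graphics)
    components: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def is_gene(self) -> bool:
        return self.type == "gene"

    @property
    def is_compound(self) -> bool:
        return self.type == "compound"

    @property
    def is_group(self) -> bool:
        return self.type == "group"


@dataclass
class Pathway:
    """A parsed KGML pathway: metadata plus ordered entries and relations.

    ``entries`` is an id-keyed insertion-ordered mapping; ``relations`` is
    an ordered list.  ``validate()`` enforces the model invariants (unique
    entry ids by construction, referential integrity of relation endpoints
    and group components, group arity).
    """

    name: str = ""
    org: str = ""
    number: str = ""
    title: str = ""
    image: str = ""
    link: str = ""
    entries: dict = field(default_factory=dict)
    relations: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def add_entry(self, entry: PathwayEntry) -> None:
        if entry.id in self.entries:
            raise KGMLValidationError(f"duplicate entry id {entry.id}")
        self.entries[entry.id] = entry

    def gene_entries(self):
        return [e for e in self.entries.values() if e.is_gene]

    def gene_ids(self):
        """Set of all gene identifiers carried by gene-type entries."""
        out = set()
        for e in self.gene_entries():
            out.update(e.names)
        return out

    def relations_from(self, entry_id: int):
        return [r for r in self.relations if r.entry1 == entry_id]

    def relations_to(self, entry_id: int):
        return [r for r in self.relations if r.entry2 == entry_id]

    def copy(self) -> "Pathway":
        return copy.deepcopy(self)

    def validate(self) -> None:
        missing = []
        for r in self.relations:
            for end in (r.entry1, r.entry2):
                if end not in self.entries:
                    missing.append(end)
        if missing:
            raise KGMLValidationError(
                "relation endpoints reference missing entry ids: "
                + ", ".join(str(i) for i in sorted(set(missing)))
            )
        for e in self.entries.values():
            if e.is_group:
                if len(e.components) < 2:
                    raise KGMLValidationError(
                        f"group entry {e.id} has fewer than 2 components"
                    )
            elif e.components:
                raise KGMLValidationError(
                    f"non-group entry {e.id} carries components"
                )
            bad = [c for c in e.components if c not in self.entries]
            if bad:
                raise KGMLValidationError(
                    f"group entry {e.id} components reference missing entry "
                    "ids: " + ", ".join(str(i) for i in sorted(set(bad)))
                )
            if not e.names:
                raise KGMLValidationError(f"entry {e.id} has an empty name list")
            if e.graphics.width <= 0 or e.graphics.height <= 0:
                raise KGMLValidationError(
                    f"entry {e.id} graphics has non-positive size"
                )


def _require(attrs: dict, key: str, context: str) -> str:
    if key not in attrs or attrs[key] == "":
        raise KGMLValidationError(f"{context} is missing mandatory attribute '{key}'")
    return attrs[key]


def _parse_graphics(el) -> Graphics:
    attrs = dict(el.attrib)
    g = Graphics(
        label=attrs.pop("name", ""),
        x=int(attrs.pop("x", 0)),
        y=int(attrs.pop("y", 0)),
        width=int(attrs.pop("width", 46)),
        height=int(attrs.pop("height", 17)),
        shape=attrs.pop("type", "rectangle"),
        fgcolor=attrs.pop("fgcolor", "#000000"),
        bgcolor=attrs.pop("bgcolor", "#FFFFFF"),
    )
    g.extra = attrs
    return g


def parse_kgml(document) -> Pathway:
    """Parse KGML text (``str`` or ``bytes``) into a validated :class:`Pathway`.

    Entries and relations preserve document order.  ``<reaction>`` elements
    (metabolic chemical networks) are skipped with a warning.  Exact
    duplicate relations are collapsed to one occurrence and logged.  Unknown
    attributes anywhere are preserved in the ``extra`` mappings and survive
    a subsequent :func:`write_kgml`.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise KGMLParseError(
            f"malformed XML at line {exc.lineno}: {exc.msg}"
        ) from exc
    if root.tag != "pathway":
        raise KGMLValidationError(f"root element is <{root.tag}>, expected <pathway>")

    attrs = dict(root.attrib)
    pathway = Pathway(
        name=attrs.pop("name", ""),
        org=attrs.pop("org", ""),
        number=attrs.pop("number", ""),
        title=attrs.pop("title", ""),
        image=attrs.pop("image", ""),
        link=attrs.pop("link", ""),
        extra=attrs,
    )

    seen_relation_keys = set()
    n_duplicates = 0
    for el in root:
        if el.tag is etree.Comment:
            continue
        if el.tag == "entry":
            eattrs = dict(el.attrib)
            eid = int(_require(eattrs, "id", "<entry>"))
            eattrs.pop("id")
            name = _require(eattrs, "name", f"<entry id={eid}>")
            eattrs.pop("name")
            etype = _require(eattrs, "type", f"<entry id={eid}>")
            eattrs.pop("type")
            link = eattrs.pop("link", "")
            graphics = Graphics()
            components = []
            for child in el:
                if child.tag == "graphics":
                    graphics = _parse_graphics(child)
                elif child.tag == "component":
                    components.append(int(_require(dict(child.attrib), "id",
                                                   f"<component> of entry {eid}")))
            names = name.split()
            if etype not in ENTRY_TYPES:
                logger.warning("entry %d has non-standard type '%s'", eid, etype)
            prefixes = {n.split(":", 1)[0] for n in names if ":" in n}
            if len(prefixes) > 1:
                logger.warning(
                    "entry %d mixes identifier namespaces: %s", eid, sorted(prefixes)
                )
            entry = PathwayEntry(
                id=eid, names=names, type=etype, link=link,
                graphics=graphics, components=components, extra=eattrs,
            )
            pathway.add_entry(entry)
        elif el.tag == "relation":
            rattrs = dict(el.attrib)
            entry1 = int(_require(rattrs, "entry1", "<relation>"))
            entry2 = int(_require(rattrs, "entry2", "<relation>"))
            rtype = _require(rattrs, "type", "<relation>")
            for k in ("entry1", "entry2", "type"):
                rattrs.pop(k)
            subtypes = []
            for child in el:
                if child.tag == "subtype":
                    sname = _require(dict(child.attrib), "name", "<subtype>")
                    subtypes.append(Subtype(sname, child.attrib.get("value", "")))
                    if sname not in SUBTYPE_NAMES:
                        logger.warning(
                            "relation %d->%d carries non-standard subtype '%s' "
                            "(preserved verbatim)", entry1, entry2, sname,
                        )
            if rtype not in RELATION_TYPES:
                logger.warning(
                    "relation %d->%d has non-standard type '%s'", entry1, entry2, rtype
                )
            relation = PathwayRelation(entry1, entry2, rtype, subtypes, rattrs)
            if relation.key() in seen_relation_keys:
                n_duplicates += 1
                logger.warning(
                    "duplicate relation %d->%d (%s) collapsed", entry1, entry2, rtype
                )
                continue
            seen_relation_keys.add(relation.key())
            pathway.relations.append(relation)
        elif el.tag == "reaction":
            logger.warning(
                "skipping <reaction> element (metabolic chemical network; "
                "only protein-interaction <relation> edges are modelled)"
            )
        else:
            logger.warning("skipping unknown element <%s>", el.tag)
    if n_duplicates:
        logger.warning("collapsed %d duplicate relation(s)", n_duplicates)
    pathway.validate()
    return pathway


def _graphics_element(g: Graphics):
    el = etree.Element("graphics")
    el.set("name", g.label)
    el.set("fgcolor", g.fgcolor)
    el.set("bgcolor", g.bgcolor)
    el.set("type", g.shape)
    el.set("x", str(g.x))
    el.set("y", str(g.y))
    el.set("width", str(g.width))
    el.set("height", str(g.height))
    for k in sorted(g.extra):
        el.set(k, str(g.extra[k]))
    return el


def write_kgml(pathway: Pathway) -> str:
    """Serialize a :class:`Pathway` back to KGML text.

    The output is deterministic for a given pathway: fixed attribute order,
    entries and relations in stored order, extra (tracking) attributes in
    sorted key order.  The pathway is validated before any output is built.
    """
    pathway.validate()
    root = etree.Element("pathway")
    for attr, value in (
        ("name", pathway.name), ("org", pathway.org), ("number", pathway.number),
        ("title", pathway.title), ("image", pathway.image), ("link", pathway.link),
    ):
        if value:
            root.set(attr, value)
    for k in sorted(pathway.extra):
        root.set(k, str(pathway.extra[k]))

    for entry in pathway.entries.values():
        el = etree.SubElement(root, "entry")
        el.set("id", str(entry.id))
        el.set("name", " ".join(entry.names))
        el.set("type", entry.type)
        if entry.link:
            el.set("link", entry.link)
        for k in sorted(entry.extra):
            el.set(k, str(entry.extra[k]))
        el.append(_graphics_element(entry.graphics))
        for comp in entry.components:
            c = etree.SubElement(el, "component")
            c.set("id", str(comp))

    for relation in pathway.relations:
        el = etree.SubElement(root, "relation")
        el.set("entry1", str(relation.entry1))
        el.set("entry2", str(relation.entry2))
        el.set("type", relation.type)
        for k in sorted(relation.extra):
            el.set(k, str(relation.extra[k]))
        for sub in relation.subtypes:
            s = etree.SubElement(el, "subtype")
            s.set("name", sub.name)
            s.set("value", sub.value)

    body = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    return body.decode("utf-8")


def fetch_kgml(
    org: str,
    number: str,
    url_template: str = DEFAULT_REST_URL,
    timeout: float = 30.0,
    opener=None,
) -> str:
    """Fetch one pathway's KGML from the KEGG REST API (academic use only).

    Parameters
    ----------
    org, number : organism code (e.g. ``"hsa"``) and pathway number
        (e.g. ``"04662"``).
    url_template : format string with ``{org}`` and ``{number}`` fields;
        override to point at a mirror.
    opener : callable ``(url, timeout) -> bytes`` replacing the default
        urllib transport (used for testing and caching layers).

    Raises
    ------
    PathwayUnavailableError
        The pathway does not exist (HTTP 404 or empty body) — the warning
        the interactive tool shows for a missing KGML.
    TransportError
        Network-level failure.
    """
    logger.info(ACADEMIC_USE_NOTICE)
    url = url_template.format(org=org, number=number)
    if opener is None:
        opener = _urllib_opener
    try:
        body = opener(url, timeout)
    except PathwayUnavailableError:
        raise PathwayUnavailableError(
            f"pathway {org}{number} does not exist in the database"
        ) from None
    if not body or not body.strip():
        raise PathwayUnavailableError(
            f"pathway {org}{number} does not exist in the database"
        )
    return body.decode("utf-8") if isinstance(body, bytes) else body


def _urllib_opener(url: str, timeout: float) -> bytes:
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            return resp.read()
    except urllib.error.HTTPError as exc:
        if exc.code in (400, 404):
            raise PathwayUnavailableError(str(exc)) from exc
        raise TransportError(f"HTTP failure fetching {url}: {exc}") from exc
    except urllib.error.URLError as exc:
        raise TransportError(f"network failure fetching {url}: {exc}") from exc
    except OSError as exc:
        raise TransportError(f"network failure fetching {url}: {exc}") from exc


def export_edge_list(pathway: Pathway) -> str:
    """Render relations as a SIF-compatible tab-delimited edge list.

    One row per relation: space-joined source entry names, an interaction
    label ``type:subtype-names``, space-joined target names.
    """
    pathway.validate()
    rows = []
    for r in pathway.relations:
        src = " ".join(pathway.entries[r.entry1].names)
        tgt = " ".join(pathway.entries[r.entry2].names)
        label = r.type
        if r.subtypes:
            label += ":" + ",".join(s.name for s in r.subtypes)
        rows.append(f"{src}\t{label}\t{tgt}")
    return "\n".join(rows) + ("\n" if rows else "")
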