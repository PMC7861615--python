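"""SBML readers and writers.

Networks are accepted in SBML Level 2 (gene associations in
``GENE_ASSOCIATION`` notes, the convention of legacy COBRA-style files)
and Level 3 with the ``fbc`` package (``geneProductAssociation``
elements).  Boolean gene logic is flattened to the set of referenced
gene identifiers: producibility is qualitative, so a reaction is kept
after gene loss as long as one associated gene survives.

Compound sets (seeds, targets, cooperation potential) travel as
species-only SBML documents, or as plain text with one identifier per
line.

Writing always emits Level 3 + fbc.  ``boundaryCondition`` attributes
are ignored on read: only the seeds define the boundary of the
expansion.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path
import libsbml

from .model import (
    CompoundSet,
    Metabolite,
    MetabolicNetwork,
    NetworkCollection,
    Reaction,
)

logger = logging.getLogger(__name__)

_GENE_ASSOC_RE = re.compile(r"GENE[_ ]ASSOCIATION:\s*([^<\n]*)", re.IGNORECASE)
_SPONTANEOUS_RE = re.compile(r"SPONTANEOUS:\s*(T|TRUE|YES|1)", re.IGNORECASE)
_GENE_TOKEN_RE = re.compile(r"[()]|\band\b|\bor\b|\bAND\b|\bOR\b")


class SBMLParseError(ValueError):
    """Malformed or inconsistent SBML input."""


def _read_document(path: str | Path) -> libsbml.SBMLDocument:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(f"{path}: {first.getMessage().strip()}")
    if doc.getModel() is None:
        raise SBMLParseError(f"{path}: no model element")
    return doc


def _genes_from_notes(rxn: libsbml.Reaction) -> frozenset[str]:
    notes = rxn.getNotesString() if rxn.isSetNotes() else ""
    m = _GENE_ASSOC_RE.search(notes)
    if not m:
        return frozenset()
    tokens = _GENE_TOKEN_RE.sub(" ", m.group(1)).split()
    return frozenset(t for t in tokens if t)


def _genes_from_fbc(rxn: libsbml.Reaction) -> frozenset[str] | None:
    plugin = rxn.getPlugin("fbc")
    if plugin is None or not plugin.isSetGeneProductAssociation():
        return None
    genes: set[str] = set()

    def walk(assoc: libsbml.FbcAssociation) -> None:
        if assoc is None:
            return
        if assoc.isFbcAnd() or assoc.isFbcOr():
            for i in range(assoc.getNumAssociations()):
                walk(assoc.getAssociation(i))
        elif assoc.isGeneProductRef():
            ref = assoc.getGeneProduct()
            if ref:
                genes.add(ref)

    walk(plugin.getGeneProductAssociation().getAssociation())
    return frozenset(genes)


def _is_spontaneous(rxn: libsbml.Reaction) -> bool:
    notes = rxn.getNotesString() if rxn.isSetNotes() else ""
    return bool(_SPONTANEOUS_RE.search(notes))


def read_network(path: str | Path, org_id: str) -> MetabolicNetwork:
    """Read one GSMN from an SBML file.

    Raises
    ------
    SBMLParseError
        On malformed XML, or when a reaction references a species
        missing from ``listOfSpecies`` (the offending reaction id is in
        the message).
    """
    if not org_id:
        raise ValueError("org_id must be non-empty")
    doc = _read_document(path)
    model = doc.getModel()
    declared: dict[str, Metabolite] = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        declared[sp.getId()] = Metabolite(
            sp.getId(), sp.getName() if sp.isSetName() else None
        )
    reactions: list[Reaction] = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        reactants = frozenset(
            rxn.getReactant(j).getSpecies() for j in range(rxn.getNumReactants())
        )
        products = frozenset(
            rxn.getProduct(j).getSpecies() for j in range(rxn.getNumProducts())
        )
        undeclared = (reactants | products) - declared.keys()
        if undeclared:
            raise SBMLParseError(
                f"{path}: reaction {rxn.getId()!r} references undeclared "
                f"species {sorted(undeclared)}"
            )
        genes = _genes_from_fbc(rxn)
        if genes is None:
            genes = _genes_from_notes(rxn)
        reversible = rxn.getReversible() if rxn.isSetReversible() else True
        reactions.append(
            Reaction(
                id=rxn.getId(),
                reactants=reactants,
                products=products,
                reversible=reversible,
                genes=genes,
                spontaneous=_is_spontaneous(rxn),
            )
        )
    return MetabolicNetwork(org_id, reactions, metabolites=declared.values())


_ORG_ID_RE = re.compile(r"[^A-Za-z0-9_]")


def sanitize_org_id(stem: str) -> str:
    return _ORG_ID_RE.sub("_", stem)


def read_collection(directory: str | Path) -> NetworkCollection:
    """Read every ``.sbml``/``.xml`` file in *directory* as one network each.

    Organism ids are the filename stems sanitized to ``[A-Za-z0-9_]``;
    a collision after sanitization is an error, as is any unreadable
    file (no silent skipping).  Per-network sizes are logged.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".sbml", ".xml")
    )
    if not files:
        raise FileNotFoundError(f"no SBML files (*.sbml, *.xml) in {directory}")
    networks = []
    seen: dict[str, Path] = {}
    for path in files:
        org_id = sanitize_org_id(path.stem)
        if org_id in seen:
            raise ValueError(
                f"org_id collision after sanitization: {path.name} and "
                f"{seen[org_id].name} both map to {org_id!r}"
            )
        seen[org_id] = path
        net = read_network(path, org_id)
        logger.info(
            "loaded %s: %d reactions, %d metabolites",
            org_id,
            len(net.reactions),
            len(net.metabolites),
        )
        networks.append(net)
    coll = NetworkCollection(networks)
    sizes = [len(n.reactions) for n in coll]
    logger.info(
        "collection of %d networks; avg reactions per GSMN %.1f",
        len(coll),
        sum(sizes) / len(sizes),
    )
    return coll


def write_network(net: MetabolicNetwork, path: str | Path) -> None:
    """Write a network as SBML Level 3 + fbc (gene associations as ORs)."""
    doc = libsbml.SBMLDocument(3, 1)
    # gene-product associations need fbc version 2
    doc.enablePackage(libsbml.FbcExtension.getXmlnsL3V1V2(), "fbc", True)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(sanitize_org_id(net.org_id))
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)
    all_genes = sorted({g for r in net for g in r.genes})
    for gene in all_genes:
        gp = mplug.createGeneProduct()
        gp.setId(gene)
        gp.setLabel(gene)
    for met in sorted(net.metabolites.values(), key=lambda m: m.id):
        sp = model.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    for rxn in sorted(net, key=lambda r: r.id):
        sr = model.createReaction()
        sr.setId(rxn.id)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for mid in sorted(rxn.reactants):
            ref = sr.createReactant()
            ref.setSpecies(mid)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for mid in sorted(rxn.products):
            ref = sr.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        if rxn.genes:
            rplug = sr.getPlugin("fbc")
            gpa = rplug.createGeneProductAssociation()
            if len(rxn.genes) == 1:
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(next(iter(rxn.genes)))
            else:
                disj = gpa.createOr()
                for gene in sorted(rxn.genes):
                    ref = disj.createGeneProductRef()
                    ref.setGeneProduct(gene)
        if rxn.spontaneous:
            sr.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                "<p>SPONTANEOUS: T</p></body>"
            )
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def write_collection(coll: NetworkCollection, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for net in coll:
        write_network(net, directory / f"{net.org_id}.sbml")


def read_compound_set(path: str | Path, label: str) -> CompoundSet:
    """Read a compound set from species-only SBML or one-id-per-line text.

    Format is sniffed from the content (an XML declaration or ``<sbml``
    root means SBML).  Duplicate identifiers collapse with a warning.
    An empty result is an error when ``label == "seeds"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.read_text(encoding="utf-8", errors="replace").lstrip()[:200]
    if head.startswith("<?xml") or head.startswith("<sbml"):
        doc = _read_document(path)
        model = doc.getModel()
        ids = [model.getSpecies(i).getId() for i in range(model.getNumSpecies())]
    else:
        ids = [
            line.strip()
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
    if len(set(ids)) < len(ids):
        warnings.warn(f"{path}: duplicate compound ids collapsed", stacklevel=2)
    return CompoundSet(label, frozenset(ids))


def write_compound_set(cs: CompoundSet, path: str | Path) -> None:
    """Write a compound set as a species-only SBML document (round-trips)."""
    if not cs.ids:
        warnings.warn(f"writing empty compound set ({cs.label})", stacklevel=2)
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(sanitize_org_id(cs.label) or "compounds")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    for mid in sorted(cs.ids):
        sp = model.createSpecies()
        sp.setId(mid)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")
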