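"""Readers and writers for CPI network inputs.

Supported dialects:

* chemical-protein link tables as distributed by large association
  databases (TSV with a chemical column, a protein column, and one or
  more integer 0-1000 score channels, gzip-transparent);
* KGML pathway XML, from which an enzyme-compound reaction network is
  derived;
* plain two-column TSV pair lists (validation positives / negatives);
* the package's own edge-list TSV + JSON sidecar round-trip format;
* compound annotation TSV and protein FASTA.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from lxml import etree

from .network import (
    BipartiteCPINetwork,
    CompoundRecord,
    DensitySummary,
    ProteinRecord,
    build_network,
    density_summary,
)

logger = logging.getLogger(__name__)


@dataclass
class IdMap:
    """Many-to-one identifier mapping; unmapped sources are tracked separately."""

    entries: dict[str, str] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)

    def __post_init__(self):
        overlap = set(self.entries) & self.unmapped
        if overlap:
            raise ValueError(f"ids both mapped and unmapped: {sorted(overlap)[:5]}")

    def resolve(self, source_id: str) -> str | None:
        """Mapped target, the id itself if unknown, or None if explicitly unmapped."""
        if source_id in self.unmapped:
            return None
        return self.entries.get(source_id, source_id)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"], dtype=str)
        entries, unmapped = {}, set()
        for row in df.itertuples(index=False):
            if pd.isna(row.target) or row.target == "":
                unmapped.add(row.source)
            else:
                entries[row.source] = row.target
        return cls(entries=entries, unmapped=unmapped)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_stitch_links(path: str | Path, id_map: IdMap | None = None) -> BipartiteCPINetwork:
    """Parse a chemical-protein links TSV into a network.

    The header must name a chemical column, a protein column and at least
    one score column. Integer scores on the database's 0-1000 scale are
    normalized to [0, 1]. With an ``id_map``, chemical ids are mapped
    (merged edges keep the maximum score per channel) and rows whose ids
    are explicitly unmapped are dropped and counted.
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.split("\t")
        lower = [c.lower() for c in cols]
        try:
            chem_idx = next(i for i, c in enumerate(lower) if "chemical" in c or c == "compound")
            prot_idx = next(i for i, c in enumerate(lower) if "protein" in c)
        except StopIteration:
            raise ValueError(f"{path}: header must name a chemical and a protein column") from None
        score_cols = [
            (i, cols[i]) for i in range(len(cols)) if i not in (chem_idx, prot_idx)
        ]
        if not score_cols:
            raise ValueError(f"{path}: no score columns in header")

        rows = []
        n_skipped = n_unmapped = 0
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                logger.warning("%s:%d: malformed row skipped", path, lineno)
                n_skipped += 1
                continue
            cid, pid = parts[chem_idx], parts[prot_idx]
            try:
                channels = {
                    name: _normalize_score(parts[i]) for i, name in score_cols
                }
            except ValueError:
                logger.warning("%s:%d: malformed score skipped", path, lineno)
                n_skipped += 1
                continue
            if id_map is not None:
                cid = id_map.resolve(cid)
                pid_resolved = id_map.resolve(pid) if pid is not None else None
                if cid is None or pid_resolved is None:
                    n_unmapped += 1
                    continue
                pid = pid_resolved
            rows.append((cid, pid, channels))

    if not rows:
        raise ValueError(f"{path}: no parsable interaction rows")
    if n_unmapped:
        logger.info("%s: dropped %d rows with unmapped identifiers", path, n_unmapped)
    compounds = {cid for cid, _, _ in rows}
    proteins = {pid for _, pid, _ in rows}
    return build_network(
        [CompoundRecord(id=c) for c in sorted(compounds)],
        [ProteinRecord(id=p) for p in sorted(proteins)],
        rows,
        provenance=str(path),
    )


def _normalize_score(raw: str) -> float:
    """Integer 0-1000 scores become 0-1; fractional scores pass through."""
    value = float(raw)
    if value > 1.0:
        value = value / 1000.0
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"score {raw!r} out of range")
    return value


# -- KGML ---------------------------------------------------------------

_ENZYME_ENTRY_TYPES = {"enzyme", "gene", "ortholog"}


def read_kgml_reaction_network(paths: Iterable[str | Path]) -> BipartiteCPINetwork:
    """Build an enzyme-compound bipartite network from KGML pathway files.

    Every reaction links each of its participating enzyme entries to each
    'C'-number substrate and product compound (direction is discarded).
    Edges are deduplicated across pathways and carry a ``kegg`` score
    channel fixed at 1.0. Glycan and drug compound entries are skipped, as
    are reactions with no mapped enzyme.
    """
    edges: set[tuple[str, str]] = set()
    n_skipped_reactions = 0
    for path in sorted(str(p) for p in paths):
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"{path}: not well-formed KGML ({exc})") from exc
        root = tree.getroot()
        # entry id -> set of enzyme names; entry id -> compound C number
        enzymes_by_reaction: dict[str, set[str]] = {}
        compounds_by_entry: dict[str, set[str]] = {}
        for entry in root.findall("entry"):
            etype = entry.get("type")
            names = (entry.get("name") or "").split()
            if etype in _ENZYME_ENTRY_TYPES:
                for rname in (entry.get("reaction") or "").split():
                    enzymes_by_reaction.setdefault(rname, set()).update(names)
            elif etype == "compound":
                cnums = {
                    n.split(":", 1)[1]
                    for n in names
                    if n.startswith("cpd:") and n.split(":", 1)[1].startswith("C")
                }
                if cnums:
                    compounds_by_entry[entry.get("id")] = cnums
        for reaction in root.findall("reaction"):
            rname = reaction.get("name")
            enzymes = set()
            for rn in (rname or "").split():
                enzymes |= enzymes_by_reaction.get(rn, set())
            if not enzymes:
                n_skipped_reactions += 1
                continue
            compounds: set[str] = set()
            for part in list(reaction.findall("substrate")) + list(reaction.findall("product")):
                compounds |= compounds_by_entry.get(part.get("id"), set())
            for enz in enzymes:
                for cpd in compounds:
                    edges.add((cpd, enz))
    if n_skipped_reactions:
        logger.info("KGML: skipped %d reactions without an enzyme mapping", n_skipped_reactions)
    compound_ids = sorted({c for c, _ in edges})
    protein_ids = sorted({e for _, e in edges})
    return build_network(
        [CompoundRecord(id=c, kegg_c_numbers={c}) for c in compound_ids],
        [ProteinRecord(id=p) for p in protein_ids],
        [(c, p, {"kegg": 1.0}) for c, p in sorted(edges)],
        provenance="KGML",
    )


def read_pair_list(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column TSV of (compound, protein) pairs, deduplicated."""
    pairs: set[tuple[str, str]] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                logger.warning("%s:%d: malformed pair row skipped", path, lineno)
                continue
            pairs.add((parts[0], parts[1]))
    return pairs


def write_pair_list(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, p in sorted(pairs):
            fh.write(f"{c}\t{p}\n")


# -- package round-trip format ------------------------------------------


def write_network(net: BipartiteCPINetwork, path: str | Path) -> None:
    """Write the edge list as TSV plus a JSON sidecar with the density summary."""
    path = Path(path)
    channels = sorted({ch for e in net.edges.values() for ch in e})
    with open(path, "w") as fh:
        fh.write("compound\tprotein\t" + "\t".join(channels) + "\n")
        for (cid, pid) in sorted(net.edges):
            scores = net.edges[(cid, pid)]
            vals = "\t".join(repr(scores.get(ch, 0.0)) for ch in channels)
            fh.write(f"{cid}\t{pid}\t{vals}\n")
    summary = density_summary(net)
    sidecar = {
        "provenance": net.provenance,
        "n_interactions": summary.n_interactions,
        "n_compounds": summary.n_compounds,
        "n_proteins": summary.n_proteins,
        "density": summary.density,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_network(path: str | Path) -> BipartiteCPINetwork:
    """Read a network written by :func:`write_network` (or any compatible TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"compound": str, "protein": str})
    channels = [c for c in df.columns if c not in ("compound", "protein")]
    rows = [
        (r.compound, r.protein, {ch: float(getattr(r, ch)) for ch in channels})
        for r in df.itertuples(index=False)
    ]
    sidecar = Path(str(path) + ".json")
    provenance = ""
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", "")
    return build_network(
        [CompoundRecord(id=c) for c in sorted(df["compound"].unique())],
        [ProteinRecord(id=p) for p in sorted(df["protein"].unique())],
        rows,
        provenance=provenance,
    )


def read_compound_annotations(path: str | Path) -> list[CompoundRecord]:
    """Compound annotation TSV: id, smiles, kegg_c, kegg_d, flags.

    Multi-valued fields are pipe-separated; empty fields mean absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for r in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                id=r.id,
                smiles=r.smiles or None,
                kegg_c_numbers=frozenset(x for x in r.kegg_c.split("|") if x),
                kegg_d_numbers=frozenset(x for x in r.kegg_d.split("|") if x),
                category_flags=frozenset(x for x in r.flags.split("|") if x),
            )
        )
    return records


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Protein sequences from FASTA, keyed by record id."""
    from Bio import SeqIO

    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
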