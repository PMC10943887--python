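"""File formats shared by the command-line interface and the tests.

FASTA goes through Biopython; structures are dot-bracket lines (blank lines
and ``#`` comments ignored); phylogenetic networks are child/parent TSV edge
lists with a separate leaf-label TSV; Newick is accepted for trees.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ModelError
from .phylo import PhyloNetwork
from .rna import SecondaryStructure, parse_dotbracket

logger = logging.getLogger(__name__)


def read_fasta(path, rna: bool = False) -> list[tuple[str, str, str]]:
    """Read FASTA records as (id, sequence, description) triples.

    With ``rna=True``, T is normalized to U (logged when it occurs).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rna and "T" in seq:
            logger.info("normalizing T to U in record %s", rec.id)
            seq = seq.replace("T", "U")
        records.append((rec.id, seq, rec.description))
    if not records:
        raise ModelError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str, str]], path) -> None:
    out = [
        SeqRecord(Seq(seq), id=rid, description=desc)
        for rid, seq, desc in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_structures(path, require_equal_length: bool = True) -> list[SecondaryStructure]:
    """One dot-bracket string per line; FASTA-style ``>`` headers, blank
    lines, and ``#`` comments are ignored."""
    structures = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith(">"):
            continue
        structures.append(parse_dotbracket(line))
    if not structures:
        raise ModelError(f"no structures in {path}")
    if require_equal_length and len({s.length for s in structures}) > 1:
        raise ModelError("structures intended for one design run differ in length")
    return structures


def read_edge_list(path) -> list[tuple[str, str]]:
    """TSV edge list, one ``child<TAB>parent`` per line."""
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ModelError(f"bad edge line: {line!r}")
        edges.append((parts[0], parts[1]))
    return edges


def read_leaf_labels(path) -> dict[str, str]:
    labels = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ModelError(f"bad label line: {line!r}")
        labels[parts[0]] = parts[1]
    return labels


def read_newick(path) -> PhyloNetwork:
    """Read a (tree-shaped) network from Newick via Biopython."""
    tree = Phylo.read(str(path), "newick")
    edges = []
    counter = [0]

    def name_of(clade):
        if clade.name:
            return clade.name
        counter[0] += 1
        clade.name = f"I{counter[0]}"
        return clade.name

    def walk(clade):
        for child in clade.clades:
            edges.append((name_of(child), name_of(clade)))
            walk(child)

    name_of(tree.root)
    walk(tree.root)
    return PhyloNetwork(edges)


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def read_config(path) -> dict:
    """Configuration / table file: JSON is canonical, YAML accepted as sugar."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ModelError(f"expected a mapping in {path}")
    return data


def write_json(data: dict, path=None, **kwargs) -> str:
    text = json.dumps(data, indent=2, **kwargs)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def header_block(config: dict) -> str:
    """Comment block declaring tool version and resolved configuration."""
    from . import __version__
    lines = [f"# treefeat {__version__}"]
    for key in sorted(config):
        lines.append(f"# {key} = {config[key]!r}")
    return "\n".join(lines) + "\n"
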