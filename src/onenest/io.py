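"""Readers and writers: plain-text split lists, NEXUS SPLITS blocks
(SplitsTree4 dialect), GraphML/GML networks, JSON reports.

All formats round-trip losslessly for canonical objects.  Parse failures
carry line numbers; weights in SPLITS blocks are accepted and ignored with
a logged notice (this package treats split systems as unweighted sets).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Tuple, Union

import networkx as nx

from .network import TAXON_KEY, UprootedNetwork
from .splits import (
    CircularOrdering,
    SplitSystem,
    make_split,
    natural_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitsParseError",
    "read_splits_text",
    "write_splits_text",
    "read_splits_nexus",
    "write_splits_nexus",
    "read_splits",
    "write_splits",
    "read_network",
    "write_network",
    "write_report",
]

PathLike = Union[str, Path]


class SplitsParseError(ValueError):
    """A malformed split file; the message names the offending line."""


# ---------------------------------------------------------------------------
# Plain text: one split per line, sides separated by "|", '#' comments.


def parse_splits_text(text: str) -> SplitSystem:
    sides = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.count("|") != 1:
            raise SplitsParseError(
                f"line {lineno}: expected exactly one '|' separator: {raw!r}"
            )
        left, right = line.split("|")
        a, b = left.split(), right.split()
        if not a or not b:
            raise SplitsParseError(f"line {lineno}: a split side is empty")
        sides.append((frozenset(a), frozenset(b)))
    if not sides:
        raise SplitsParseError("no splits found")
    ground = frozenset().union(*(a | b for a, b in sides))
    for i, (a, b) in enumerate(sides, start=1):
        if a | b != ground:
            raise SplitsParseError(
                f"split {i} does not cover the ground set "
                f"{sorted(ground, key=natural_key)}"
            )
        if a & b:
            raise SplitsParseError(f"split {i} has overlapping sides")
    return SplitSystem.from_sides([a for a, _ in sides], ground)


def read_splits_text(path: PathLike) -> SplitSystem:
    return parse_splits_text(Path(path).read_text())


def format_splits_text(sigma: SplitSystem) -> str:
    lines = [f"# {len(sigma)} splits on {sigma.n_taxa} taxa"]
    lines.extend(str(s) for s in sigma)
    return "\n".join(lines) + "\n"


def write_splits_text(sigma: SplitSystem, path: PathLike) -> None:
    Path(path).write_text(format_splits_text(sigma))


# ---------------------------------------------------------------------------
# NEXUS (SplitsTree4 SPLITS block dialect)


def format_splits_nexus(
    sigma: SplitSystem, cycle: Optional[CircularOrdering] = None
) -> str:
    taxa = sorted(sigma.ground, key=natural_key)
    index = {t: i + 1 for i, t in enumerate(taxa)}
    out = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={len(taxa)};", "TAXLABELS"]
    out.extend(f"  [{i + 1}] '{t}'" for i, t in enumerate(taxa))
    out.append(";")
    out.append("END;")
    out.append("")
    out.append("BEGIN SPLITS;")
    out.append(f"DIMENSIONS NTAX={len(taxa)} NSPLITS={len(sigma)};")
    out.append("FORMAT LABELS=NO WEIGHTS=YES;")
    if cycle is not None:
        out.append("CYCLE " + " ".join(str(index[t]) for t in cycle) + ";")
    out.append("MATRIX")
    for i, s in enumerate(sigma, start=1):
        members = " ".join(str(index[t]) for t in sorted(s.block, key=natural_key))
        out.append(f"[{i}, size={s.size}]\t1.0\t{members},")
    out.append(";")
    out.append("END;")
    return "\n".join(out) + "\n"


def write_splits_nexus(
    sigma: SplitSystem, path: PathLike, cycle: Optional[CircularOrdering] = None
) -> None:
    Path(path).write_text(format_splits_nexus(sigma, cycle=cycle))


def parse_splits_nexus(text: str) -> Tuple[SplitSystem, Optional[CircularOrdering]]:
    lines = text.splitlines()
    if not lines or not lines[0].strip().upper().startswith("#NEXUS"):
        raise SplitsParseError("line 1: not a NEXUS file (missing #NEXUS)")
    taxa: dict = {}
    sides = []
    cycle_idx: Optional[list] = None
    block = None
    in_taxlabels = False
    in_matrix = False
    saw_weights = False
    for lineno, raw in enumerate(lines, start=1):
        line = _strip_nexus_comments(raw).strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("BEGIN"):
            block = upper.replace("BEGIN", "").replace(";", "").strip()
            continue
        if upper.startswith("END"):
            block = None
            in_taxlabels = in_matrix = False
            continue
        if block == "TAXA":
            if upper.startswith("TAXLABELS"):
                in_taxlabels = True
                line = line[len("TAXLABELS") :].strip()
                if not line:
                    continue
            if in_taxlabels:
                done = line.endswith(";")
                for tok in line.rstrip(";").split():
                    taxa[len(taxa) + 1] = tok.strip("'\"")
                if done:
                    in_taxlabels = False
        elif block == "SPLITS":
            if upper.startswith("FORMAT"):
                saw_weights = "WEIGHTS=YES" in upper.replace(" ", "")
            elif upper.startswith("CYCLE"):
                toks = line.rstrip(";").split()[1:]
                try:
                    cycle_idx = [int(t) for t in toks]
                except ValueError:
                    raise SplitsParseError(f"line {lineno}: malformed CYCLE statement")
            elif upper.startswith("MATRIX"):
                in_matrix = True
            elif in_matrix:
                if line == ";":
                    in_matrix = False
                    continue
                row = line.rstrip(",;").split()
                idx = []
                for tok in row:
                    try:
                        idx.append(int(tok))
                    except ValueError:
                        try:
                            float(tok)  # a weight; ignored
                        except ValueError:
                            raise SplitsParseError(
                                f"line {lineno}: unexpected token {tok!r} in MATRIX"
                            )
                if not idx:
                    raise SplitsParseError(f"line {lineno}: empty split row")
                sides.append((lineno, idx))
        # unknown blocks are skipped silently
    if not taxa:
        raise SplitsParseError("no TAXA block found")
    if not sides:
        raise SplitsParseError("no SPLITS matrix found")
    if saw_weights:
        logger.info("split weights present in NEXUS input; ignored")
    ground = frozenset(taxa.values())
    split_sides = []
    for lineno, idx in sides:
        bad = [i for i in idx if i not in taxa]
        if bad:
            raise SplitsParseError(f"line {lineno}: taxon index {bad[0]} out of range")
        split_sides.append({taxa[i] for i in idx})
    system = SplitSystem.from_sides(split_sides, ground)
    ordering = None
    if cycle_idx is not None:
        bad = [i for i in cycle_idx if i not in taxa]
        if bad:
            raise SplitsParseError(f"CYCLE: taxon index {bad[0]} out of range")
        ordering = CircularOrdering.from_sequence([taxa[i] for i in cycle_idx])
    return system, ordering


def _strip_nexus_comments(line: str) -> str:
    out = []
    depth = 0
    for ch in line:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(0, depth - 1)
        elif depth == 0:
            out.append(ch)
    return "".join(out)


def read_splits_nexus(path: PathLike) -> Tuple[SplitSystem, Optional[CircularOrdering]]:
    return parse_splits_nexus(Path(path).read_text())


def read_splits(path: PathLike) -> SplitSystem:
    """Dispatch on extension: .nex/.nexus -> NEXUS, anything else plain text."""
    p = Path(path)
    if p.suffix.lower() in {".nex", ".nexus"}:
        return read_splits_nexus(p)[0]
    return read_splits_text(p)


def write_splits(
    sigma: SplitSystem, path: PathLike, cycle: Optional[CircularOrdering] = None
) -> None:
    p = Path(path)
    if p.suffix.lower() in {".nex", ".nexus"}:
        write_splits_nexus(sigma, p, cycle=cycle)
    else:
        write_splits_text(sigma, p)


# ---------------------------------------------------------------------------
# Networks (GraphML primary, GML accepted on read)


def write_network(net: UprootedNetwork, path: PathLike) -> None:
    p = Path(path)
    # GML reserves "label" for the node name, so taxa travel as "taxon" there
    key = TAXON_KEY if p.suffix.lower() == ".gml" else "label"
    g = nx.Graph()
    for v, data in net.graph.nodes(data=True):
        if TAXON_KEY in data:
            g.add_node(str(v), **{key: data[TAXON_KEY]})
        else:
            g.add_node(str(v))
    for u, v in net.graph.edges():
        g.add_edge(str(u), str(v))
    if p.suffix.lower() == ".gml":
        nx.write_gml(g, p)
    else:
        nx.write_graphml(g, p, infer_numeric_types=True)


def read_network(path: PathLike) -> UprootedNetwork:
    p = Path(path)
    if p.suffix.lower() == ".gml":
        raw = nx.read_gml(p, label="id")
    else:
        raw = nx.read_graphml(p)
    g = nx.Graph()
    for v, data in raw.nodes(data=True):
        label = data.get(TAXON_KEY) or data.get("label")
        if raw.degree(v) == 1:
            if not label:
                raise SplitsParseError(f"leaf vertex {v!r} carries no label")
            g.add_node(v, **{TAXON_KEY: str(label)})
        else:
            g.add_node(v)
    g.add_edges_from(raw.edges())
    g = nx.convert_node_labels_to_integers(g)
    return UprootedNetwork(g)


def write_report(report: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
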