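"""Domain types and readers/writers for every file format the pipeline touches.

Gene identifiers are opaque, case-sensitive strings throughout.  Mapping
probe sets, protein accessions or symbol aliases into a single namespace
is the caller's job; no normalization is attempted here.

Formats: 2-column edge-list TSV or 3-column SIF for interaction networks,
GMT for gene panels and pathway annotations, a 3-column component TSV
(component_id, pathway_id, comma-separated members), and expression TSV
(genes x samples, log scale) with a 2-column sample/group design file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Undirected simple graph over gene-identifier strings.  The interaction
#: network, the CFNN and every common-module subnetwork are all instances.
GeneNetwork = nx.Graph


class ParseError(ValueError):
    """Structurally invalid input file."""


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene identifiers (susceptibility panel, DEG set, ...)."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GenePanel":
        return cls(name=name, genes=frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PathwayAnnotation:
    """A pathway with its member genes.

    ``category`` is free text (e.g. a disease vs. functional subclass);
    in GMT files it is carried in the description column.
    """

    pathway_id: str
    display_name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has no member genes")


@dataclass(frozen=True)
class ComponentDefinition:
    """A pathway-diagram node: one or more interchangeable proteins.

    A component with more than one member gene is a multi-protein
    component; it counts as differentially expressed if any member is.
    """

    component_id: str
    pathway_id: str
    member_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError(f"component {self.component_id!r} has no members")

    @property
    def is_multi_protein(self) -> bool:
        return len(self.member_genes) > 1


@dataclass
class ExpressionMatrix:
    """Log-scale expression values (genes x samples) with a two-group design.

    ``values`` rows are genes, columns are samples; ``groups`` maps each
    sample to 'case' or 'control'.  Both groups need at least two samples.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.groups.index):
            raise ValueError("sample columns and design rows do not match")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in ("case", "control"):
            if (self.groups == grp).sum() < 2:
                raise ValueError(f"group {grp!r} has fewer than 2 samples")

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])


# ---------------------------------------------------------------------------
# networks


def read_edge_list(path: str | Path, dialect: str = "tsv") -> GeneNetwork:
    """Read an undirected simple graph from a 2-column TSV or 3-column SIF.

    Self-loops and duplicate (unordered) edges are dropped with a logged
    count.  SIF middle column (interaction type) is ignored.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    want = 2 if dialect == "tsv" else 3
    net = nx.Graph()
    n_self, n_dup, n_lines = 0, 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != want:
                raise ParseError(
                    f"{path}: line {lineno}: expected {want} columns, "
                    f"got {len(fields)}"
                )
            u, v = fields[0], fields[-1]
            n_lines += 1
            if u == v:
                n_self += 1
                continue
            if net.has_edge(u, v):
                n_dup += 1
                continue
            net.add_edge(u, v)
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path, n_self, n_dup,
        )
    if n_lines == 0:
        logger.warning("%s: empty edge list", path)
    return net


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write sorted 2-column TSV; isolated nodes are not representable."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def _read_gmt_rows(path: str | Path) -> list[tuple[str, str, list[str]]]:
    rows = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs name, description "
                    f"and at least one gene ({len(fields)} fields found)"
                )
            name, desc = fields[0], fields[1]
            if name in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate name {name!r}")
            seen.add(name)
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            rows.append((name, desc, genes))
    return rows


def read_gmt(path: str | Path) -> list[GenePanel]:
    """Read gene panels from GMT (description column ignored)."""
    return [
        GenePanel.from_iterable(name, genes)
        for name, _desc, genes in _read_gmt_rows(path)
    ]


def write_gmt(panels: Iterable[GenePanel], path: str | Path,
              description: str = "-") -> None:
    with open(path, "w") as fh:
        for p in panels:
            fh.write("\t".join([p.name, description, *sorted(p.genes)]) + "\n")


def read_pathways_gmt(path: str | Path) -> list[PathwayAnnotation]:
    """Read pathway annotations from GMT.

    The description column carries the free-text category; the display
    name defaults to the pathway id.
    """
    return [
        PathwayAnnotation(
            pathway_id=name, display_name=name, category=desc,
            genes=frozenset(genes),
        )
        for name, desc, genes in _read_gmt_rows(path)
    ]


def write_pathways_gmt(pathways: Iterable[PathwayAnnotation],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write(
                "\t".join([p.pathway_id, p.category or "-", *sorted(p.genes)])
                + "\n"
            )


# ---------------------------------------------------------------------------
# pathway components

_COMPONENT_HEADER = ["component_id", "pathway_id", "genes"]


def read_components(path: str | Path) -> list[ComponentDefinition]:
    """Read component definitions from TSV (header row required)."""
    comps: list[ComponentDefinition] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COMPONENT_HEADER:
            raise ParseError(
                f"{path}: expected header {_COMPONENT_HEADER}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(fields)}"
                )
            cid, pid, members = fields
            comps.append(
                ComponentDefinition(
                    component_id=cid, pathway_id=pid,
                    member_genes=frozenset(
                        g for g in members.split(",") if g
                    ),
                )
            )
    return comps


def write_components(comps: Iterable[ComponentDefinition],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COMPONENT_HEADER) + "\n")
        for c in comps:
            fh.write(
                f"{c.component_id}\t{c.pathway_id}\t"
                + ",".join(sorted(c.member_genes)) + "\n"
            )


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample/group design TSV.

    Samples are restricted to those present in both files (drops logged);
    duplicate gene rows are mean-averaged, mirroring the probe-set rule
    for multiple probes mapping to one gene.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    if list(design.columns) != ["sample", "group"]:
        raise ParseError(
            f"{design_path}: expected columns ['sample', 'group'], "
            f"got {list(design.columns)}"
        )
    groups = design.set_index("sample")["group"]
    if groups.index.has_duplicates:
        raise ParseError(f"{design_path}: duplicate sample ids in design")

    shared = [s for s in values.columns if s in groups.index]
    dropped = (set(values.columns) | set(groups.index)) - set(shared)
    if dropped:
        logger.warning(
            "dropping %d sample(s) absent from matrix or design: %s",
            len(dropped), sorted(dropped),
        )
    values = values[shared]
    groups = groups.loc[shared]

    if values.index.has_duplicates:
        values = values.groupby(level=0, sort=False).mean()

    for grp in ("case", "control"):
        if (groups == grp).sum() < 2:
            raise ParseError(
                f"fewer than 2 {grp!r} samples after joining matrix and design"
            )
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     design_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6f")
    design = pd.DataFrame(
        {"sample": expr.groups.index, "group": expr.groups.values}
    )
    design.to_csv(design_path, sep="\t", index=False)
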