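"""Readers, writers and typed records for every external format the pipeline touches.

All downstream modules consume only the types defined here.  Genomic
coordinates are normalized to 0-based half-open intervals at ingestion;
only readers and writers convert, so no other module ever reasons about
coordinate conventions.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TECopyRecord",
    "IntervalRecord",
    "PhyloTree",
    "SpeciesTraitTable",
    "TE_CLASSES",
    "parse_repeatmasker_out",
    "read_tree",
    "read_intervals",
    "write_intervals",
    "read_trait_table",
    "load_fig_wasp_traits",
]

#: The collapsed TE class taxonomy used throughout (finer family names are
#: retained verbatim on each record).
TE_CLASSES = ("DNA", "LINE", "SINE", "LTR", "RC", "Unknown")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class TECopyRecord:
    """One annotated TE copy from a repeat-annotation table.

    ``perc_div`` is the percent divergence of the copy from its family
    consensus (the quantity the insertion-time pipeline dates).  Values
    at or above 75% are outside the domain of the multiple-hit
    correction and are rejected at construction.
    """

    scaffold: str
    start: int  # 1-based inclusive, as annotated
    end: int  # 1-based inclusive
    strand: str
    family_name: str
    te_class: str
    perc_div: float
    score: int = 0
    overlaps_higher_scoring: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for {self.scaffold}:{self.start}-{self.end}")
        if not (0.0 <= self.perc_div < 75.0):
            raise ValueError(
                f"perc_div {self.perc_div} outside [0, 75); the divergence "
                "correction is undefined at or beyond 75%"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown te_class {self.te_class!r}")

    @property
    def copy_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IntervalRecord:
    """A genomic interval, stored 0-based half-open regardless of source format."""

    scaffold: str
    start: int
    end: int
    kind: str = "TE"  # gene | TE | CRM
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.scaffold}:[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def _collapse_te_class(class_family: str) -> str:
    """Map a RepeatMasker class/family string onto the six-label taxonomy."""
    head = class_family.split("/")[0].strip("?")
    if head in ("DNA", "LINE", "SINE", "LTR", "RC"):
        return head
    return "Unknown"


def parse_repeatmasker_out(
    path: str | Path,
    min_score: int | None = None,
) -> list[TECopyRecord]:
    """Parse a RepeatMasker ``.out`` annotation table.

    Parameters
    ----------
    path
        File in the standard ``.out`` layout: three header lines followed by
        whitespace-delimited annotation rows.
    min_score
        Optional Smith–Waterman score threshold; rows scoring below it are
        dropped.  The default keeps every row.

    Returns
    -------
    One :class:`TECopyRecord` per annotation line.  ``C`` strands are mapped
    to ``-``; rows flagged with a trailing asterisk (overlapped by a
    higher-scoring match) are retained with ``overlaps_higher_scoring=True``.
    """
    path = Path(path)
    records: list[TECopyRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    # Standard layout: two header lines and one blank line before data.
    body = lines[3:] if len(lines) >= 3 else []
    if not body:
        warnings.warn(f"{path}: no annotation lines found", stacklevel=2)
        return records
    for lineno, line in enumerate(body, start=4):
        fields = line.split()
        if not fields:
            continue
        if len(fields) < 14:
            raise ParseError(
                f"{path}:{lineno}: expected >= 14 whitespace-delimited columns, "
                f"got {len(fields)}"
            )
        try:
            score = int(fields[0])
            perc_div = float(fields[1])
            scaffold = fields[4]
            start = int(fields[5])
            end = int(fields[6])
            strand = fields[8]
            family = fields[9]
            class_family = fields[10]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if min_score is not None and score < min_score:
            continue
        records.append(
            TECopyRecord(
                scaffold=scaffold,
                start=start,
                end=end,
                strand="-" if strand == "C" else strand,
                family_name=family,
                te_class=_collapse_te_class(class_family),
                perc_div=perc_div,
                score=score,
                overlaps_higher_scoring=fields[-1] == "*",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Phylogenies
# ---------------------------------------------------------------------------


class PhyloTree:
    """A rooted phylogeny with branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` adding the matrix views the
    comparative methods need: the Brownian-motion covariance (shared
    root-to-node path lengths) and its Pagel-lambda transform.
    """

    def __init__(self, tree: dendropy.Tree, *, ultrametric_tol: float = 1e-6):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(
                    f"branch leading to {_node_label(edge.head_node)} has no length"
                )
            if edge.length < 0:
                raise ValueError(
                    f"negative branch length on branch leading to "
                    f"{_node_label(edge.head_node)}"
                )
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        for i, node in enumerate(tree.preorder_internal_node_iter()):
            if not node.label:
                node.label = f"node{i}"
        depths = np.array([self.root_to_tip(t) for t in labels])
        self.is_ultrametric = bool(
            depths.size and np.ptp(depths) <= ultrametric_tol * max(depths.max(), 1.0)
        )

    # -- basic views --------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def root_to_tip(self, label: str) -> float:
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf.distance_from_root()
        raise KeyError(f"tip {label!r} not in tree")

    @property
    def depth(self) -> float:
        return max(self.root_to_tip(t) for t in self.tip_labels)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- covariance machinery ------------------------------------------------

    def cov_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Shared root-to-MRCA path length matrix C (the BM covariance basis).

        ``C[i, j]`` is the summed branch length from the root to the most
        recent common ancestor of tips *i* and *j*; the diagonal holds
        root-to-tip distances.
        """
        labels = list(order) if order is not None else self.tip_labels
        leaves = {leaf.taxon.label: leaf for leaf in self._tree.leaf_node_iter()}
        missing = [l for l in labels if l not in leaves]
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        # ancestor depth map per leaf
        anc: dict[str, dict[int, float]] = {}
        for lab in labels:
            node = leaves[lab]
            d: dict[int, float] = {}
            depth = node.distance_from_root()
            d[id(node)] = depth
            p = node
            while p.parent_node is not None:
                p = p.parent_node
                d[id(p)] = p.distance_from_root()
            anc[lab] = d
        n = len(labels)
        C = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i, n):
                b = labels[j]
                shared = set(anc[a]) & set(anc[b])
                C[i, j] = C[j, i] = max(anc[a][k] for k in shared)
        return C

    def lambda_cov(self, lam: float, order: Sequence[str] | None = None) -> np.ndarray:
        """Pagel-lambda transform: off-diagonals scaled by ``lam``, diagonal kept."""
        C = self.cov_matrix(order)
        Cl = lam * C
        np.fill_diagonal(Cl, np.diag(C))
        return Cl

    def internal_node_labels(self) -> list[str]:
        """Labels of internal nodes in preorder (assigned at construction)."""
        return [n.label for n in self._tree.preorder_internal_node_iter()]


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or "<internal>"


def read_tree(source: str | Path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths.

    A basal polytomy is treated as an unrooted tree and rejected; internal
    polytomies elsewhere are preserved.
    """
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    if len(tree.seed_node.child_nodes()) != 2:
        raise ValueError(
            "tree root has degree != 2; supply a rooted tree (basal "
            "polytomies are read as unrooted)"
        )
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


def read_intervals(
    path: str | Path, format: str = "BED", kind: str = "TE"
) -> list[IntervalRecord]:
    """Read genomic intervals from BED (0-based half-open) or GFF3 (1-based
    inclusive), normalizing everything to 0-based half-open."""
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"format must be BED or GFF3, got {format!r}")
    out: list[IntervalRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t") if "\t" in line else line.split()
        try:
            if fmt == "BED":
                scaffold, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else "."
            else:  # GFF3: 1-based inclusive -> [s-1, e)
                scaffold = f[0]
                start, end = int(f[3]) - 1, int(f[4])
                name = _gff3_id(f[8]) if len(f) > 8 else "."
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if end <= start:
            raise ParseError(
                f"{path}:{lineno}: interval [{start},{end}) empty after normalization"
            )
        out.append(IntervalRecord(scaffold, start, end, kind=kind, name=name))
    return out


def _gff3_id(attributes: str) -> str:
    for part in attributes.split(";"):
        if part.startswith(("ID=", "Name=")):
            return part.split("=", 1)[1]
    return "."


def write_intervals(records: Iterable[IntervalRecord], path: str | Path) -> None:
    """Write intervals as BED4 (the internal convention is already BED's)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.name}\n")


def intervals_to_frame(records: Sequence[IntervalRecord]) -> pd.DataFrame:
    """PyRanges-style frame (Chromosome/Start/End/Name) for interval analytics."""
    return pd.DataFrame(
        {
            "Chromosome": [r.scaffold for r in records],
            "Start": [r.start for r in records],
            "End": [r.end for r in records],
            "Name": [r.name for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Species trait tables
# ---------------------------------------------------------------------------

REQUIRED_TRAIT_COLUMNS = (
    "species",
    "group",
    "oviposition_site",
    "genome_size",
    "te_length",
    "te_count",
    "te_family_count",
    "te_content",
    "r",
)


class SpeciesTraitTable:
    """Per-species trait table: genome size (Mb), TE length (Mb), TE counts,
    TE content (%), oviposition site, and the substitution rate r
    (substitutions/site/My).  Backed by a pandas DataFrame indexed by species."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_TRAIT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"trait table missing required columns: {missing}")
        frame = frame.copy()
        frame["group"] = pd.Categorical(frame["group"])
        frame["oviposition_site"] = pd.Categorical(
            frame["oviposition_site"], categories=["inside", "outside"]
        )
        if (frame["te_length"] > frame["genome_size"]).any():
            bad = frame.loc[frame["te_length"] > frame["genome_size"], "species"]
            raise ValueError(f"te_length exceeds genome_size for: {list(bad)}")
        if ((frame["te_content"] < 0) | (frame["te_content"] > 100)).any():
            raise ValueError("te_content outside [0, 100]")
        if (frame["r"] <= 0).any():
            raise ValueError("substitution rate r must be positive")
        self.frame = frame.set_index("species", drop=False)

    def __len__(self) -> int:
        return len(self.frame)

    def values_by_group(self, column: str) -> dict[str, np.ndarray]:
        return {
            str(g): sub[column].to_numpy()
            for g, sub in self.frame.groupby("group", observed=True)
        }

    def __getitem__(self, column: str) -> pd.Series:
        return self.frame[column]


def read_trait_table(path: str | Path) -> SpeciesTraitTable:
    """Read a TSV species trait table (see :data:`REQUIRED_TRAIT_COLUMNS`).

    An optional ``mu`` column (substitutions/site/generation) is carried
    through when present; an empty one is dropped.
    """
    frame = pd.read_csv(path, sep="\t")
    if "mu" in frame.columns and frame["mu"].isna().all():
        frame = frame.drop(columns=["mu"])
    return SpeciesTraitTable(frame)


def load_fig_wasp_traits() -> SpeciesTraitTable:
    """The packaged 11-species fig-wasp trait table (6 pollinators, 5
    non-pollinating fig wasps) with TE annotation summaries and per-species
    substitution rates."""
    here = Path(__file__).parent / "data" / "table1_fig_wasps.tsv"
    return read_trait_table(here)
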