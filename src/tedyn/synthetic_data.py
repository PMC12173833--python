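"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: TE copies whose
divergences derive from dated insertion bursts (so the dating pipeline can
be tested against true ages), Yule trees, Brownian-motion and clumped
binary traits on trees, and planted gene/TE/CRM interval sets.

Ages are converted to divergences with the exact algebraic inverse of the
dating correction (K = 200 r T percent, D = 75(1 - exp(-K/75))) rather
than by simulating sequences: the unit under test is the dating pipeline,
not a sequence evolver.  All generators are seed-deterministic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io_formats import IntervalRecord, PhyloTree, read_tree
from .te_landscape import kimura_forward

__all__ = [
    "BurstSpec",
    "TraitSimSpec",
    "simulate_te_copies",
    "simulate_tree",
    "simulate_bm_trait",
    "simulate_binary_trait",
    "make_interval_fixtures",
]


@dataclass(frozen=True)
class BurstSpec:
    """Ground truth for one TE insertion burst: ``n_copies`` copies of
    ``family_name`` inserted at ages Normal(age_mean, age_sd) My (truncated
    at zero), each of length Normal(length_mean, length_sd) bases."""

    family_name: str
    te_class: str = "LTR"
    n_copies: int = 100
    age_mean: float = 20.0
    age_sd: float = 2.0
    length_mean: float = 500.0
    length_sd: float = 50.0
    rate_r: float = 0.0049

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.age_mean < 0:
            raise ValueError("age_mean must be >= 0")
        if self.rate_r <= 0:
            raise ValueError("rate_r must be positive")


@dataclass(frozen=True)
class TraitSimSpec:
    """Continuous-trait simulation settings: Brownian motion with variance
    rate ``sigma2``, optional Pagel-lambda rescaling of the covariance."""

    model: str = "BM"  # BM | lambda-BM
    sigma2: float = 1.0
    root_value: float = 0.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")


_RM_CLASS = {
    "DNA": "DNA/hAT",
    "LINE": "LINE/RTE-X",
    "SINE": "SINE/tRNA",
    "LTR": "LTR/Gypsy",
    "RC": "RC/Helitron",
    "Unknown": "Unknown",
}

_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query    matching"
    "  repeat        position in repeat\n"
    "score   div. del. ins.  sequence  begin  end   (left)  repeat"
    "    class/family  begin  end    (left)  ID\n"
    "\n"
)


def simulate_te_copies(
    bursts: list[BurstSpec], seed: int
) -> tuple[str, pd.DataFrame]:
    """Generate RepeatMasker ``.out`` text for a set of insertion bursts.

    Returns the ``.out`` text and a truth ledger with one row per copy
    (family, te_class, true_age, copy_length, perc_div, scaffold, start,
    end).  Raises if any implied divergence reaches the 75% correction
    ceiling — use a smaller age or rate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for b in bursts:
        if b.age_sd > 0:
            ages = truncnorm.rvs(
                -b.age_mean / b.age_sd, np.inf, loc=b.age_mean, scale=b.age_sd,
                size=b.n_copies, random_state=rng,
            )
        else:
            ages = np.full(b.n_copies, float(b.age_mean))
        K = 200.0 * b.rate_r * ages  # percent corrected divergence
        D = kimura_forward(K)
        # the forward map saturates at 75; refuse anything close enough to
        # break the correction's domain after text formatting
        if np.any(D >= 74.995):
            raise ValueError(
                f"burst {b.family_name!r} implies divergence >= 75%; "
                "reduce age_mean/age_sd or rate_r"
            )
        lengths = np.maximum(
            np.round(rng.normal(b.length_mean, b.length_sd, size=b.n_copies)), 1
        ).astype(int) if b.length_sd > 0 else np.full(b.n_copies, int(b.length_mean))
        for age, div, length in zip(ages, D, lengths):
            rows.append((b.family_name, b.te_class, b.rate_r, age, length, div))
    pos = 1
    recs = []
    for i, (fam, cls, r, age, length, div) in enumerate(rows):
        start, end = pos, pos + length - 1
        pos = end + 100
        recs.append(
            {
                "family": fam,
                "te_class": cls,
                "rate_r": r,
                "true_age": age,
                "copy_length": length,
                "perc_div": div,
                "scaffold": "scf1",
                "start": start,
                "end": end,
            }
        )
    ledger = pd.DataFrame(recs)
    buf = io.StringIO()
    buf.write(_OUT_HEADER)
    for i, rec in enumerate(recs, start=1):
        # divergences carry full precision so dating round-trips are exact
        buf.write(
            f"{1000:5d} {rec['perc_div']:.12f}  0.0  0.0  {rec['scaffold']}"
            f"  {rec['start']}  {rec['end']}  (0)  +  {rec['family']}"
            f"  {_RM_CLASS[rec['te_class']]}  1  {rec['copy_length']}  (0)  {i}\n"
        )
    return buf.getvalue(), ledger


def simulate_tree(n_tips: int, seed: int, model: str = "yule") -> PhyloTree:
    """Simulate an ultrametric rooted tree of unit total depth.

    Pure-birth (Yule) process: exponential waiting times between
    speciations, a final Exp(n) epoch after the last split so terminal
    branches are strictly positive, then depth rescaled to 1.
    """
    if model.lower() != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("children", "start", "end", "label")

        def __init__(self, start):
            self.children, self.start, self.end, self.label = [], start, None, None

    root = _N(0.0)
    active = [_N(0.0), _N(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        node.end = t
        kids = [_N(t), _N(t)]
        node.children = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / n_tips)
    labels = iter(f"t{i+1}" for i in range(n_tips))
    for node in active:
        node.end = t_end
        node.label = next(labels)

    def newick(node) -> str:
        length = (node.end - node.start) / t_end
        if not node.children:
            return f"{node.label}:{length:.10f}"
        return "(" + ",".join(newick(c) for c in node.children) + f"):{length:.10f}"

    s = "(" + ",".join(newick(c) for c in root.children) + ");"
    return read_tree_from_string(s)


def read_tree_from_string(newick: str) -> PhyloTree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    return PhyloTree(tree)


def simulate_bm_trait(
    tree: PhyloTree, spec: TraitSimSpec, seed: int, size: int = 1
) -> pd.DataFrame:
    """Tip values from the multivariate normal N(root_value, sigma2 * C(lambda)).

    C is the shared-path-length matrix of the tree; lambda scales its
    off-diagonals (lambda = 0 gives i.i.d. tips on an ultrametric tree).
    Returns a (size x n_tips) frame, one replicate per row.
    """
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    lam = spec.lam if spec.model == "lambda-BM" else 1.0
    C = tree.lambda_cov(lam, labels) * spec.sigma2
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(labels)))
    Z = rng.standard_normal((size, len(labels)))
    X = spec.root_value + Z @ L.T
    return pd.DataFrame(X, columns=labels)


def simulate_binary_trait(
    tree: PhyloTree,
    mode: str,
    prevalence: float,
    seed: int,
    max_retries: int = 100,
) -> pd.Series:
    """A binary tip trait, either phylogenetically clumped or random.

    ``clumped`` plants state 1 on a union of whole clades chosen greedily
    (largest first, random among equals) until the prevalence count is
    reached — super-Brownian aggregation of the kind the oviposition trait
    shows.  A thresholded Brownian draw would by construction match the D
    statistic's zero reference rather than be clumped relative to it.
    ``random`` draws i.i.d. Bernoulli(prevalence) states, resampling up to
    ``max_retries`` times if the draw is monomorphic.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly between 0 and 1")
    labels = tree.tip_labels
    n = len(labels)
    rng = np.random.default_rng(seed)
    if mode == "clumped":
        k = int(np.clip(round(prevalence * n), 1, n - 1))
        clades = []  # tip sets of every node (leaves included)
        for node in tree.dendropy_tree.preorder_node_iter():
            tips = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(tips) <= n - 1:  # exclude the root's full set
                clades.append(tips)
        chosen: set[str] = set()
        while len(chosen) < k:
            room = k - len(chosen)
            usable = [c for c in clades if len(c) <= room and not (c & chosen)]
            top = max(len(c) for c in usable)
            pick = [c for c in usable if len(c) == top]
            chosen |= set(pick[rng.integers(len(pick))])
        states = np.array([1 if lab in chosen else 0 for lab in labels])
        return pd.Series(states, index=labels)
    if mode == "random":
        for _ in range(max_retries):
            states = (rng.random(n) < prevalence).astype(int)
            if 0 < states.sum() < n:
                return pd.Series(states, index=labels)
        raise RuntimeError(
            f"could not draw a polymorphic trait in {max_retries} attempts"
        )
    raise ValueError(f"mode must be 'clumped' or 'random', got {mode!r}")


def make_interval_fixtures(
    n_genes: int,
    n_tes: int,
    n_crms: int,
    scaffold_length: int,
    overlap_plan: dict[str, int] | None = None,
    seed: int = 0,
    scaffold: str = "scf1",
) -> tuple[list[IntervalRecord], list[IntervalRecord], list[IntervalRecord], pd.DataFrame]:
    """Plant gene, TE and CRM intervals with a known overlap configuration.

    ``overlap_plan`` maps {"within": a, "contains": b, "partial": c} to the
    number of TE/CRM pairs planted in each configuration (TE inside CRM,
    CRM inside TE, partial overlap); remaining TEs and CRMs are placed
    disjointly.  The ledger records the true configuration of every
    planted pair.  Raises if the features do not fit on the scaffold.
    """
    plan = dict(overlap_plan or {})
    for key in plan:
        if key not in ("within", "contains", "partial"):
            raise ValueError(f"unknown overlap_plan key {key!r}")
    n_pairs = sum(plan.values())
    if n_pairs > min(n_tes, n_crms):
        raise ValueError("overlap plan requires more TEs or CRMs than requested")
    rng = np.random.default_rng(seed)
    slot = 1200
    n_slots = n_genes + n_tes + n_crms  # pairs share a slot, so this is generous
    if n_slots * slot > scaffold_length:
        raise ValueError(
            f"{n_slots} features need {n_slots * slot} bp; scaffold is "
            f"{scaffold_length} bp"
        )
    genes: list[IntervalRecord] = []
    tes: list[IntervalRecord] = []
    crms: list[IntervalRecord] = []
    ledger_rows = []
    cursor = 0
    te_i = crm_i = 0

    def _next_slot():
        nonlocal cursor
        s = cursor + int(rng.integers(0, 100))
        cursor += slot
        return s

    for config, count in plan.items():
        for _ in range(count):
            s = _next_slot()
            te_name, crm_name = f"te{te_i}", f"crm{crm_i}"
            te_i += 1
            crm_i += 1
            if config == "within":
                crm = IntervalRecord(scaffold, s, s + 400, "CRM", crm_name)
                te = IntervalRecord(scaffold, s + 100, s + 300, "TE", te_name)
                truth = "te_within_crm"
            elif config == "contains":
                te = IntervalRecord(scaffold, s, s + 400, "TE", te_name)
                crm = IntervalRecord(scaffold, s + 100, s + 300, "CRM", crm_name)
                truth = "crm_within_te"
            else:
                te = IntervalRecord(scaffold, s, s + 200, "TE", te_name)
                crm = IntervalRecord(scaffold, s + 100, s + 300, "CRM", crm_name)
                truth = "partial"
            tes.append(te)
            crms.append(crm)
            ledger_rows.append({"te": te_name, "crm": crm_name, "config": truth})
    for _ in range(n_tes - te_i):
        s = _next_slot()
        tes.append(IntervalRecord(scaffold, s, s + 300, "TE", f"te{te_i}"))
        te_i += 1
    for _ in range(n_crms - crm_i):
        s = _next_slot()
        crms.append(IntervalRecord(scaffold, s, s + 300, "CRM", f"crm{crm_i}"))
        crm_i += 1
    for g in range(n_genes):
        s = _next_slot()
        genes.append(IntervalRecord(scaffold, s, s + 600, "gene", f"gene{g}"))
    ledger = pd.DataFrame(ledger_rows, columns=["te", "crm", "config"])
    return genes, tes, crms, ledger
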