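"""Topology selection among candidate trees, NNI refinement, and
nonparametric bootstrap split support.

Full maximum-likelihood tree search is replaced by evaluation of a named
candidate set (optionally refined by nearest-neighbor-interchange search):
in the long-branch-attraction questions this package targets, only a small
number of resolutions compete, and tallying which named candidate wins per
replicate is the quantity of scientific interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Alignment, Node, Split, Tree, TreeError, extract_splits, unroot
from .inference import (
    LikelihoodResult,
    PruningEngine,
    log_likelihood,
    optimize_branch_lengths,
    pmsf_model,
)
from .models import SiteModel

logger = logging.getLogger("lbasim")


@dataclass
class CandidateSet:
    """Named alternative topologies over one shared leaf set."""

    trees: dict[str, Tree]

    def __post_init__(self):
        if len(self.trees) < 2:
            raise TreeError("need at least two candidate topologies")
        leaf_sets = {name: frozenset(t.leaf_names())
                     for name, t in self.trees.items()}
        ref = next(iter(leaf_sets.values()))
        for name, s in leaf_sets.items():
            if s != ref:
                raise TreeError(f"candidate {name!r} has a different leaf set")

    @property
    def names(self) -> list[str]:
        return list(self.trees)

    def __getitem__(self, name: str) -> Tree:
        return self.trees[name]

    def items(self):
        return self.trees.items()


@dataclass
class EvaluationResult:
    winner: str
    loglik: dict[str, float]
    fitted: dict[str, Tree] = field(repr=False)
    results: dict[str, LikelihoodResult] = field(repr=False, default=None)

    def __iter__(self):  # unpack like (winner, loglik)
        return iter((self.winner, self.loglik))


def evaluate_candidates(alignment: Alignment, model: SiteModel,
                        candidates: CandidateSet, optimize: bool = True,
                        tol: float = 1e-4, max_cycles: int = 20,
                        xatol: float = 1e-4,
                        starts: dict[str, Tree] | None = None
                        ) -> EvaluationResult:
    """Score every candidate; the winner is the argmax log-likelihood.

    Ties break deterministically in favor of earlier candidate order.
    ``starts`` optionally provides warm-start branch lengths per candidate
    (same topologies, e.g. trees fitted under a cheaper model).
    """
    loglik: dict[str, float] = {}
    fitted: dict[str, Tree] = {}
    results: dict[str, LikelihoodResult] = {}
    for name, tree in candidates.items():
        if starts and name in starts:
            tree = starts[name]
        if optimize:
            ftree, res = optimize_branch_lengths(
                tree, alignment, model, tol=tol, max_cycles=max_cycles,
                xatol=xatol)
        else:
            ftree, res = tree, log_likelihood(tree, alignment, model)
        loglik[name] = res.total
        fitted[name] = ftree
        results[name] = res
    winner = max(loglik, key=lambda n: (loglik[n], -candidates.names.index(n)))
    # max() keeps the first of equals already because strict > is required
    return EvaluationResult(winner, loglik, fitted, results)


def evaluate_candidates_pmsf(alignment: Alignment, mixture_model: SiteModel,
                             candidates: CandidateSet,
                             guide_model: SiteModel | None = None,
                             guide_eval: EvaluationResult | None = None,
                             tol: float = 1e-4, max_cycles: int = 20,
                             xatol: float = 1e-4):
    """Two-pass PMSF candidate evaluation under a profile-mixture model.

    First pass: fit the (cheap) homogeneous guide model to every candidate
    and take the winner's fitted tree as the guide (a pre-computed
    ``guide_eval`` may be supplied instead).  Second pass: compute
    posterior mean site frequency profiles on the guide and evaluate all
    candidates under the resulting per-site-profile model, warm-started
    from the guide's fitted branch lengths.  Returns
    ``(EvaluationResult, guide EvaluationResult)``.
    """
    if mixture_model.frequency_mode != "mixture":
        raise ValueError("PMSF evaluation needs a mixture model")
    if guide_eval is None:
        guide_model = guide_model or SiteModel.lg_g(
            alpha=mixture_model.gamma.alpha
            if np.isfinite(mixture_model.gamma.alpha) else 1.0,
            k=mixture_model.gamma.k, empirical_from=alignment)
        guide_eval = evaluate_candidates(alignment, guide_model, candidates,
                                         optimize=True, tol=tol,
                                         max_cycles=max_cycles, xatol=xatol)
    guide_tree = guide_eval.fitted[guide_eval.winner]
    site_model = pmsf_model(alignment, guide_tree, mixture_model.mixture,
                            mixture_model.exchangeabilities,
                            mixture_model.gamma)
    final = evaluate_candidates(alignment, site_model, candidates,
                                optimize=True, tol=tol,
                                max_cycles=max_cycles, xatol=xatol,
                                starts=guide_eval.fitted)
    return final, guide_eval


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------


def _split_signature(tree: Tree) -> frozenset:
    return frozenset(extract_splits(tree))


def nni_neighbors(tree: Tree) -> list[Tree]:
    """All distinct nearest-neighbor-interchange rearrangements.

    Works on the unrooted form; each internal edge contributes two
    alternative topologies (duplicates are removed by split signature).
    """
    base = unroot(tree)
    neighbors: dict[frozenset, Tree] = {}
    base_sig = _split_signature(base)

    # parent map over the working copy
    def walk(node, parent, acc):
        acc.append((node, parent))
        for c in node.children:
            walk(c, node, acc)

    nodes: list[tuple[Node, Node | None]] = []
    walk(base.root, None, nodes)
    parent_of = {id(n): p for n, p in nodes}

    for node, parent in nodes:
        if parent is None or node.is_leaf:
            continue  # internal (non-root) node <-> parent defines the edge
        siblings = [c for c in parent.children if c is not node]
        sib = siblings[0]
        for child in list(node.children):
            # swap `sib` (attached to parent) with `child` (attached to node)
            parent.children[parent.children.index(sib)] = child
            node.children[node.children.index(child)] = sib
            sig = _split_signature(base)
            if sig != base_sig and sig not in neighbors:
                neighbors[sig] = base.copy()
            # swap back
            node.children[node.children.index(sib)] = child
            parent.children[parent.children.index(child)] = sib
    return list(neighbors.values())


def nni_search(start: Tree, alignment: Alignment, model: SiteModel,
               max_rounds: int = 20, improve_tol: float = 1e-4,
               tol: float = 1e-3, max_cycles: int = 8,
               xatol: float = 1e-3) -> Tree:
    """Greedy best-improvement NNI hill climb from ``start``.

    Each round scores every NNI neighbor (branch lengths re-optimized) and
    accepts the best if it improves the log-likelihood by more than
    ``improve_tol``; stops at a local optimum.  The returned tree's
    likelihood is never below the start tree's.
    """
    current, res = optimize_branch_lengths(start, alignment, model, tol=tol,
                                           max_cycles=max_cycles, xatol=xatol)
    best_ll = res.total
    seen: dict[frozenset, tuple[float, Tree]] = {
        _split_signature(current): (best_ll, current)}
    for round_no in range(max_rounds):
        improved = False
        best_tree = None
        for neigh in nni_neighbors(current):
            sig = _split_signature(neigh)
            if sig in seen:
                ll, ftree = seen[sig]
            else:
                ftree, fres = optimize_branch_lengths(
                    neigh, alignment, model, tol=tol, max_cycles=max_cycles,
                    xatol=xatol)
                ll = fres.total
                seen[sig] = (ll, ftree)
            if ll > best_ll + improve_tol:
                best_ll, best_tree = ll, ftree
                improved = True
        if not improved:
            break
        current = best_tree
        logger.debug("NNI round %d: logL %.4f", round_no + 1, best_ll)
    return current


def random_binary_tree(taxa, rng: np.random.Generator,
                       branch_length: float = 0.1) -> Tree:
    """Random topology by sequential random addition (uniform attachment)."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise TreeError("need at least 3 taxa")
    order = list(rng.permutation(len(taxa)))
    root = Node(None, 0.0, [Node(taxa[order[0]], branch_length),
                            Node(taxa[order[1]], branch_length),
                            Node(taxa[order[2]], branch_length)])
    tree = Tree(root)
    for i in order[3:]:
        edges = [n for n in tree.postorder() if n is not root]
        target = edges[rng.integers(len(edges))]

        def attach(node):
            for j, c in enumerate(node.children):
                if c is target:
                    mid = Node(None, c.length / 2, [c])
                    c.length /= 2
                    mid.children.append(Node(taxa[i], branch_length))
                    node.children[j] = mid
                    return True
                if attach(c):
                    return True
            return False

        attach(root)
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class SupportTable:
    """Bootstrap frequencies (in [0, 1]) for named splits."""

    frequencies: dict[str, float]
    n_replicates: int

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("split_name\tfrequency\tn_reps\n")
            for name, f in self.frequencies.items():
                fh.write(f"{name}\t{f:.6g}\t{self.n_replicates}\n")


def bootstrap_support(alignment: Alignment, model: SiteModel,
                      candidates: CandidateSet,
                      splits_of_interest: dict[str, Split],
                      n_reps: int, seed, optimize: bool = False,
                      tol: float = 1e-3, max_cycles: int = 8) -> SupportTable:
    """Nonparametric (site-resampling) bootstrap over the candidate set.

    Each replicate resamples ``n_sites`` columns with replacement, selects
    the winning candidate, and credits every split of interest present in
    the winner's topology.  With ``optimize=False`` (default) candidate
    branch lengths are first fitted once on the original alignment and each
    replicate re-scores candidates by resampled site log-likelihood sums --
    equivalent to running the evaluation with fixed branch lengths, at a
    fraction of the cost.  With ``optimize=True`` branch lengths are
    re-optimized within every replicate.
    """
    rng = np.random.default_rng(seed)
    names = candidates.names
    cand_splits = {name: extract_splits(candidates[name])
                   for name in names}
    hits = {label: 0 for label in splits_of_interest}
    n_sites = alignment.n_sites

    if optimize:
        for rep in range(n_reps):
            idx = rng.integers(n_sites, size=n_sites)
            res = evaluate_candidates(alignment.take_sites(idx), model,
                                      candidates, optimize=True, tol=tol,
                                      max_cycles=max_cycles)
            for label, split in splits_of_interest.items():
                if split in cand_splits[res.winner]:
                    hits[label] += 1
    else:
        base = evaluate_candidates(alignment, model, candidates,
                                   optimize=True, tol=tol,
                                   max_cycles=max_cycles)
        site_ll = np.vstack([base.results[name].per_site for name in names])
        for rep in range(n_reps):
            counts = np.bincount(rng.integers(n_sites, size=n_sites),
                                 minlength=n_sites).astype(float)
            totals = site_ll @ counts
            winner = names[int(np.argmax(totals))]
            for label, split in splits_of_interest.items():
                if split in cand_splits[winner]:
                    hits[label] += 1

    freqs = {label: hits[label] / n_reps for label in splits_of_interest}
    return SupportTable(freqs, n_reps)
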