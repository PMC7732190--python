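"""Experiment drivers: branch-length bias, topology recovery, composite
mixing, monophyly-based gene ranking, taxon removal, and cross-validation.

Every driver is a pure function of its configuration and seed: replicate
seeds are spawned deterministically, so all tables are exactly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Alignment,
    Split,
    Tree,
    TreeError,
    extract_splits,
    prune_taxa,
    unroot,
)
from .inference import (
    log_likelihood,
    optimize_branch_lengths,
    optimize_mixture_weights,
)
from .models import SiteModel
from .simulate import simulate_alignment, simulate_ensemble
from .topology import (
    CandidateSet,
    evaluate_candidates,
    evaluate_candidates_pmsf,
    nni_search,
    random_binary_tree,
)

logger = logging.getLogger("lbasim")


def _spawn_rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Branch-length discrepancy
# ---------------------------------------------------------------------------


def _split_lengths(tree: Tree) -> dict[Split, float]:
    """Length of every internal branch keyed by its split."""
    t = unroot(tree)
    all_taxa = frozenset(t.leaf_names())
    leafsets: dict[int, frozenset] = {}
    out: dict[Split, float] = {}
    for node in t.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset([node.name])
            continue
        s = frozenset().union(*(leafsets[id(c)] for c in node.children))
        leafsets[id(node)] = s
        if node is not t.root and 2 <= len(s) <= len(all_taxa) - 2:
            out[Split(s, all_taxa - s)] = node.length
    return out


def clade_mean_depth(tree: Tree, taxa) -> float:
    """Mean distance from each clade member to the clade's common ancestor.

    The common ancestor is the node whose subtree holds exactly the clade;
    requires the clade to be a proper subtree of the (arbitrarily rooted)
    tree, which holds for all trees this package generates.
    """
    taxa = frozenset(taxa)
    target = None
    for node in tree.postorder():
        if frozenset(leaf.name for leaf in _subtree_leaves(node)) == taxa:
            target = node
            break
    if target is None:
        raise TreeError(f"clade {sorted(taxa)} is not a subtree")
    depths = []

    def walk(node, depth):
        if node.is_leaf:
            depths.append(depth)
        for c in node.children:
            walk(c, depth + c.length)

    walk(target, 0.0)
    return float(np.mean(depths))


def _subtree_leaves(node):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def branch_length_experiment(tree: Tree, gen_model: SiteModel,
                             infer_models: dict[str, SiteModel],
                             n_sites: int, seed,
                             tol: float = 1e-4, max_cycles: int = 30,
                             fit_alpha: bool = False) -> pd.DataFrame:
    """Simulate once, refit branch lengths under each model, compare to truth.

    Returns one row per (quantity, model): internal branches keyed by their
    split and named clades by mean member-to-ancestor distance.
    """
    if not tree.clades:
        raise TreeError("tree must carry named clades")
    aln, _ = simulate_alignment(tree, gen_model, n_sites, seed)

    truth_splits = _split_lengths(tree)
    truth_clades = {name: clade_mean_depth(tree, taxa)
                    for name, taxa in tree.clades.items()}

    rows = []
    for model_name, model in infer_models.items():
        fitted, res = optimize_branch_lengths(
            tree, aln, model, tol=tol, max_cycles=max_cycles,
            optimize_alpha=fit_alpha)
        logger.info("branch_length_experiment: %s logL=%.2f",
                    model_name, res.total)
        est_splits = _split_lengths(fitted)
        for split, truth in truth_splits.items():
            rows.append({
                "quantity": repr(split), "kind": "internal",
                "model": model_name, "estimate": est_splits[split],
                "truth": truth,
            })
        for clade_name, taxa in tree.clades.items():
            rows.append({
                "quantity": clade_name, "kind": "clade",
                "model": model_name,
                "estimate": clade_mean_depth(fitted, taxa),
                "truth": truth_clades[clade_name],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Topology recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryRow:
    generating: str
    gen_model: str
    infer_model: str
    stratum: str
    taxon_set: str
    counts: dict[str, int]
    n_replicates: int
    bootstrap_median: dict[str, float] | None = None

    def __post_init__(self):
        if sum(self.counts.values()) != self.n_replicates:
            raise ValueError("winner counts must sum to n_replicates")

    def fraction(self, name: str) -> float:
        return self.counts.get(name, 0) / self.n_replicates


@dataclass
class RecoveryTable:
    rows: list[RecoveryRow] = field(default_factory=list)
    #: per-replicate records: (replicate, infer_model, winner, logL margin
    #: of the winner over the best rival candidate)
    replicates: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "generating": r.generating, "gen_model": r.gen_model,
                "infer_model": r.infer_model, "stratum": r.stratum,
                "taxon_set": r.taxon_set, "n_replicates": r.n_replicates,
            }
            for name, c in r.counts.items():
                rec[f"wins_{name}"] = c
            if r.bootstrap_median:
                for name, v in r.bootstrap_median.items():
                    rec[f"bs_{name}"] = v
            recs.append(rec)
        return pd.DataFrame(recs)

    def row(self, infer_model: str) -> RecoveryRow:
        for r in self.rows:
            if r.infer_model == infer_model:
                return r
        raise KeyError(infer_model)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_winners_tsv(self, path) -> None:
        """Per-replicate winners: replicate, model, winner, logL margin."""
        with open(path, "w") as fh:
            fh.write("replicate\tinfer_model\twinner\tlogL_margin\n")
            for rec in self.replicates:
                fh.write(f"{rec['replicate']}\t{rec['infer_model']}\t"
                         f"{rec['winner']}\t{rec['logL_margin']:.6g}\n")


def recovery_experiment(candidates: CandidateSet, generating: str,
                        gen_models, infer_models: dict[str, SiteModel],
                        n_replicates: int, n_sites: int, seed,
                        jitter_sd: float = 0.05,
                        pmsf_for_mixtures: bool = True,
                        use_nni: bool = False,
                        drop_taxa=None,
                        stratum: str = "all",
                        tol: float = 1e-3, max_cycles: int = 8,
                        xatol: float = 1e-3) -> RecoveryTable:
    """Simulate replicates on one candidate and tally which candidate wins.

    ``gen_models`` is a SiteModel or a list of them (the parameter-set
    ensemble); per-replicate branch-length jitter emulates spread across
    posterior parameter draws.  Mixture-mode inference models are evaluated
    through the two-pass PMSF protocol when ``pmsf_for_mixtures`` is set;
    with ``use_nni`` the winner is refined by NNI search and replicates
    whose refined tree matches no candidate are tallied as ``"other"``.
    ``drop_taxa`` prunes both the simulated alignments and the candidates
    before inference (the long-branch taxon-removal variant).
    """
    if generating not in candidates.names:
        raise KeyError(f"generating topology {generating!r} not a candidate")
    if isinstance(gen_models, SiteModel):
        gen_models = [gen_models]
    gen_tree = candidates[generating]
    alignments = simulate_ensemble(gen_tree, gen_models, n_sites,
                                   n_replicates, seed, jitter_sd=jitter_sd)

    eval_candidates = candidates
    if drop_taxa:
        pruned = {name: prune_taxa(t, None, drop_taxa)[0]
                  for name, t in candidates.items()}
        eval_candidates = CandidateSet(pruned)
        keep = [t for t in alignments[0].taxa if t not in set(drop_taxa)]
        alignments = [a.subset_taxa(keep) for a in alignments]

    cand_sigs = {name: frozenset(extract_splits(t))
                 for name, t in eval_candidates.items()}

    # homogeneous models double as the PMSF guide pass, so evaluate them
    # first within each replicate and reuse the fits
    model_order = sorted(infer_models,
                         key=lambda n: infer_models[n].frequency_mode == "mixture")
    counts = {name: {n: 0 for n in eval_candidates.names}
              for name in infer_models}
    records: list[dict] = []
    for r, aln in enumerate(alignments):
        hom_eval = None
        for model_name in model_order:
            model = infer_models[model_name]
            if model.frequency_mode == "mixture" and pmsf_for_mixtures:
                ev, hom_eval = evaluate_candidates_pmsf(
                    aln, model, eval_candidates, guide_eval=hom_eval,
                    tol=tol, max_cycles=max_cycles, xatol=xatol)
            else:
                ev = evaluate_candidates(aln, model, eval_candidates,
                                         optimize=True, tol=tol,
                                         max_cycles=max_cycles, xatol=xatol)
                if model.frequency_mode == "single" and hom_eval is None:
                    hom_eval = ev
            winner = ev.winner
            if use_nni:
                refined = nni_search(ev.fitted[winner], aln, model,
                                     tol=tol, max_cycles=max_cycles)
                sig = frozenset(extract_splits(refined))
                winner = next((n for n, s in cand_sigs.items() if s == sig),
                              "other")
            counts[model_name][winner] = counts[model_name].get(winner, 0) + 1
            rivals = [v for n, v in ev.loglik.items() if n != ev.winner]
            records.append({
                "replicate": r, "infer_model": model_name, "winner": winner,
                "logL_margin": ev.loglik[ev.winner] - max(rivals),
            })
            logger.info("recovery %s rep %d/%d -> %s",
                        model_name, r + 1, n_replicates, winner)
    table = RecoveryTable(replicates=records)
    for model_name in infer_models:
        table.rows.append(RecoveryRow(
            generating=generating,
            gen_model=gen_models[0].describe(),
            infer_model=model_name, stratum=stratum,
            taxon_set="pruned" if drop_taxa else "all",
            counts=counts[model_name], n_replicates=n_replicates))
    return table


# ---------------------------------------------------------------------------
# Composite mixing
# ---------------------------------------------------------------------------


def mixing_experiment(tree_a: Tree, model_a: SiteModel,
                      tree_b: Tree, model_b: SiteModel,
                      proportions, n_pairs: int, n_sites: int,
                      infer_model: SiteModel, seed,
                      names: tuple[str, str] = ("A", "B"),
                      tol: float = 1e-3, max_cycles: int = 6,
                      xatol: float = 1e-3) -> pd.DataFrame:
    """Winner tallies for composite alignments mixing two simulations.

    For each pair, one alignment is simulated on each topology; at
    proportion ``p`` the composite takes ``round(p * n_sites)`` sites drawn
    without replacement from the first and the remainder from the second.
    """
    proportions = list(proportions)
    if any(p < 0 or p > 1 for p in proportions):
        raise ValueError("proportions must lie in [0, 1]")
    candidates = CandidateSet({names[0]: tree_a, names[1]: tree_b})
    use_pmsf = infer_model.frequency_mode == "mixture"
    rows = []
    for pair in range(n_pairs):
        rng = _spawn_rng(seed, pair)
        aln_a, _ = simulate_alignment(tree_a, model_a, n_sites, None, rng=rng)
        aln_b, _ = simulate_alignment(tree_b, model_b, n_sites, None, rng=rng)
        aln_b = aln_b.subset_taxa(aln_a.taxa)
        for p in proportions:
            n_a = int(round(p * n_sites))
            idx_a = rng.choice(n_sites, size=n_a, replace=False)
            idx_b = rng.choice(n_sites, size=n_sites - n_a, replace=False)
            composite = Alignment(
                list(aln_a.taxa),
                np.hstack([aln_a.data[:, idx_a], aln_b.data[:, idx_b]]))
            if use_pmsf:
                ev, _ = evaluate_candidates_pmsf(
                    composite, infer_model, candidates, tol=tol,
                    max_cycles=max_cycles, xatol=xatol)
            else:
                ev = evaluate_candidates(composite, infer_model, candidates,
                                         optimize=True, tol=tol,
                                         max_cycles=max_cycles, xatol=xatol)
            rows.append({"pair": pair, "proportion": p, "winner": ev.winner})
        logger.info("mixing pair %d/%d done", pair + 1, n_pairs)
    df = pd.DataFrame(rows)
    out = (df.groupby("proportion")["winner"]
           .value_counts().unstack(fill_value=0))
    for n in names:
        if n not in out:
            out[n] = 0
    out = out.rename(columns={names[0]: "wins_a", names[1]: "wins_b"})
    return out.reset_index()[["proportion", "wins_a", "wins_b"]]


# ---------------------------------------------------------------------------
# Monophyly-based gene ranking
# ---------------------------------------------------------------------------


@dataclass
class MonophylyScore:
    gene_id: int
    score: int        # reference clades recovered monophyletic
    n_clades: int     # clades scoreable for this gene

    def __post_init__(self):
        if not 0 <= self.score <= self.n_clades:
            raise ValueError("score must lie in [0, n_clades]")

    @property
    def normalized(self) -> float:
        return self.score / self.n_clades if self.n_clades else 0.0


def monophyly_rank(genes, reference_clades: dict[str, frozenset],
                   infer_model: SiteModel, seed,
                   nni_rounds: int = 20,
                   tol: float = 5e-2, max_cycles: int = 2):
    """Rank genes by how many reference clades their gene trees recover.

    Each gene tree is an NNI hill climb from a random-addition start under
    ``infer_model``.  Clades not fully present in a gene's taxa are skipped
    and the score normalized over the scoreable ones.  Returns the ranked
    score list (stable sort, best first, ties by gene order) plus the
    pooled best and worst quarters (by sites of the ranked concatenation).
    """
    from .core import is_monophyletic

    genes = list(genes)
    if len(genes) < 4:
        raise ValueError("need at least 4 genes to form quarters")
    scores = []
    for g, aln in enumerate(genes):
        rng = _spawn_rng(seed, g)
        start = random_binary_tree(aln.taxa, rng)
        gtree = nni_search(start, aln, infer_model, max_rounds=nni_rounds,
                           tol=tol, max_cycles=max_cycles)
        taxa = set(aln.taxa)
        scoreable = {name: members
                     for name, members in reference_clades.items()
                     if set(members) <= taxa and len(members) >= 2}
        score = sum(is_monophyletic(gtree, members)
                    for members in scoreable.values())
        scores.append(MonophylyScore(g, score, len(scoreable)))
        logger.info("gene %d monophyly %d/%d", g, score, len(scoreable))

    ranked = sorted(scores, key=lambda s: -s.normalized)  # stable: ties by order
    concat = Alignment.concatenate([genes[s.gene_id] for s in ranked])
    quarter = concat.n_sites // 4
    best = concat.take_sites(np.arange(quarter))
    worst = concat.take_sites(np.arange(concat.n_sites - quarter,
                                        concat.n_sites))
    return ranked, best, worst


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CrossValidationResult:
    deltas: np.ndarray    # test logL(A) - test logL(B), one per repetition
    mean: float
    sd: float
    n_reps: int
    winner: str

    def __post_init__(self):
        if abs(self.mean - float(np.mean(self.deltas))) > 1e-9:
            raise ValueError("mean must equal the mean of the repetitions")


def cross_validation(alignment: Alignment, tree: Tree,
                     model_a: SiteModel, model_b: SiteModel,
                     train_sites: int = 10000, test_sites: int = 2000,
                     n_reps: int = 10, seed=0,
                     names: tuple[str, str] = ("A", "B"),
                     fit_alpha: bool = True,
                     optimize_weights: bool = False,
                     mixture_via_pmsf: bool = True,
                     tol: float = 1e-2, max_cycles: int = 10,
                     xatol: float = 1e-3) -> CrossValidationResult:
    """Model comparison by held-out site log-likelihood on a fixed topology.

    Per repetition, disjoint train/test site sets are drawn; each model's
    continuous parameters (branch lengths, gamma shape, optionally mixture
    weights) are fitted on the training sites and scored on the test sites.

    With ``mixture_via_pmsf`` (default), branch lengths and shape for a
    mixture model are optimized under its PMSF per-site approximation on
    the training sites (guide tree = homogeneous fit of the same topology);
    held-out scoring always uses the full mixture likelihood, which is
    transferable across site sets where per-site profiles are not.
    """
    if train_sites + test_sites > alignment.n_sites:
        raise ValueError("train + test exceeds available sites")
    deltas = []
    for rep in range(n_reps):
        rng = _spawn_rng(seed, rep)
        idx = rng.choice(alignment.n_sites, size=train_sites + test_sites,
                         replace=False)
        train = alignment.take_sites(idx[:train_sites])
        test = alignment.take_sites(idx[train_sites:])
        test_ll = {}
        for name, model in zip(names, (model_a, model_b)):
            scoring_model = model
            if model.frequency_mode == "mixture" and mixture_via_pmsf:
                from .inference import pmsf_model

                guide_alpha = (model.gamma.alpha
                               if np.isfinite(model.gamma.alpha) else 1.0)
                guide = SiteModel.lg_g(alpha=guide_alpha, k=model.gamma.k,
                                       empirical_from=train)
                guide_tree, _ = optimize_branch_lengths(
                    tree, train, guide, tol=tol, max_cycles=max_cycles,
                    xatol=xatol)
                psm = pmsf_model(train, guide_tree, model.mixture,
                                 model.exchangeabilities, model.gamma)
                fitted_tree, res = optimize_branch_lengths(
                    guide_tree, train, psm, tol=tol, max_cycles=max_cycles,
                    optimize_alpha=fit_alpha, xatol=xatol)
                if fit_alpha and model.gamma.k > 1:
                    scoring_model = model.with_alpha(res.model.gamma.alpha)
            else:
                fitted_tree, res = optimize_branch_lengths(
                    tree, train, model, tol=tol, max_cycles=max_cycles,
                    optimize_alpha=fit_alpha, xatol=xatol)
                scoring_model = res.model
            if optimize_weights and scoring_model.frequency_mode == "mixture":
                scoring_model = optimize_mixture_weights(
                    fitted_tree, train, scoring_model)
            test_ll[name] = log_likelihood(fitted_tree, test,
                                           scoring_model).total
        deltas.append(test_ll[names[0]] - test_ll[names[1]])
        logger.info("cross-validation rep %d: delta logL = %.2f",
                    rep + 1, deltas[-1])
    deltas = np.asarray(deltas)
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1)) if n_reps > 1 else 0.0
    winner = names[0] if mean >= 0 else names[1]
    return CrossValidationResult(deltas, mean, sd, n_reps, winner)
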