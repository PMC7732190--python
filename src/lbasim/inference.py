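"""Likelihood computation and optimization on a fixed topology.

Per-site likelihoods are computed by Felsenstein pruning under all three
frequency modes (single profile, finite profile mixture, per-site PMSF
profiles), with discrete-gamma rate categories and per-node rescaling of
conditional vectors to avoid underflow.  Transition probabilities use the
spectral decomposition of the reversible rate matrix, which also enables a
cheap one-dimensional profile of the likelihood along any single branch:
with partials folded into the eigenbasis the per-site likelihood is a dot
product with ``exp(lam * t)``, so coordinate-wise branch optimization costs
one small GEMV per trial length.

Branch lengths are optimized by exact coordinate ascent over edges in an
Euler-tour order: "down" partials are refreshed on subtree exit and "up"
partials are threaded along the tour, so every one-dimensional optimization
sees the exact likelihood and the total log-likelihood is monotone
non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .core import GAP_CODE, Alignment, Tree, TreeError, unroot
from .models import (
    ExchangeabilityMatrix,
    GammaRates,
    ProfileMixture,
    SiteModel,
    discrete_gamma,
)

logger = logging.getLogger("lbasim")

BRANCH_BOUNDS = (1e-8, 20.0)
_TINY = 1e-300


@dataclass
class LikelihoodResult:
    """Total and per-site log-likelihoods for one (tree, model, data) triple."""

    total: float
    per_site: np.ndarray
    model: SiteModel = field(repr=False)
    tree: Tree = field(repr=False)
    converged: bool = True
    n_cycles: int = 0

    def write_site_loglik_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("site\tlogL\n")
            for i, v in enumerate(self.per_site):
                fh.write(f"{i}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# Flattened tree
# ---------------------------------------------------------------------------


class _FlatTree:
    """Index-based view of a Tree: leaves 0..L-1 (alignment order), then
    internal nodes in postorder, root last."""

    def __init__(self, tree: Tree, taxa: list[str]):
        self.tree = tree  # owned copy; lengths written back by sync()
        leaf_index = {t: i for i, t in enumerate(taxa)}
        tree_leaves = set(tree.leaf_names())
        if tree_leaves != set(taxa):
            raise TreeError(
                "tree leaves and alignment taxa differ: "
                f"{sorted(tree_leaves ^ set(taxa))}")
        self.n_leaves = len(taxa)
        nodes: list = [None] * self.n_leaves
        order: list[int] = []

        def assign(node) -> int:
            if node.is_leaf:
                idx = leaf_index[node.name]
                nodes[idx] = node
                return idx
            kids = [assign(c) for c in node.children]
            nodes.append(node)
            idx = len(nodes) - 1
            self._children[idx] = kids
            order.append(idx)
            return idx

        self._children: dict[int, list[int]] = {}
        self.root = assign(tree.root)
        self.n_nodes = len(nodes)
        self.nodes = nodes
        self.children = [self._children.get(i, []) for i in range(self.n_nodes)]
        self.postorder_internal = order  # root last
        self.lengths = np.array([n.length for n in nodes])

    def sync(self) -> Tree:
        """Write the length array back into the owned Tree and return it."""
        for n, t in zip(self.nodes, self.lengths):
            n.length = float(t)
        self.nodes[self.root].length = 0.0
        return self.tree


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------


class PruningEngine:
    """Pruning likelihoods and branch optimization for one data set.

    Site patterns are compressed (identical columns share one computation)
    except in per-site-profile mode, where every column carries its own
    stationary profile.
    """

    def __init__(self, tree: Tree, alignment: Alignment, model: SiteModel):
        self.alignment = alignment
        self.model = model
        self.per_site_mode = model.frequency_mode == "per_site"
        if self.per_site_mode and model.site_profiles.shape[0] != alignment.n_sites:
            raise ValueError("need one site profile per alignment column")
        self.flat = _FlatTree(tree.copy(), alignment.taxa)

        data = alignment.data
        if self.per_site_mode:
            self.patterns = data
            self.pattern_index = np.arange(alignment.n_sites)
            self.counts = np.ones(alignment.n_sites)
        else:
            patterns, inverse, counts = np.unique(
                data, axis=1, return_inverse=True, return_counts=True)
            self.patterns = patterns
            self.pattern_index = inverse.ravel()
            self.counts = counts.astype(float)
        self.n_patterns = self.patterns.shape[1]

        # leaf conditionals, shared across mixture components and rates
        eye = np.vstack([np.eye(20), np.ones(20)])
        self.leaf_cond = [
            np.ascontiguousarray(eye[self.patterns[i]])
            for i in range(self.flat.n_leaves)
        ]

        self._prepare_components()
        self.set_rates(model.gamma.rates)

    # -- model preparation -------------------------------------------------

    def _prepare_components(self):
        """Batched spectral decomposition of every component's rate matrix."""
        model = self.model
        ex = model.exchangeabilities.values
        profs = np.atleast_2d(model.component_profiles())
        pis = np.maximum(profs, 1e-10)
        pis = pis / pis.sum(axis=1, keepdims=True)

        q = ex[None, :, :] * pis[:, None, :]
        diag = np.arange(20)
        q[:, diag, diag] = -q.sum(axis=2)
        scale = -(pis * q[:, diag, diag]).sum(axis=1)
        q /= scale[:, None, None]
        sq = np.sqrt(pis)
        sym = q * (sq[:, :, None] / sq[:, None, :])
        sym = (sym + sym.transpose(0, 2, 1)) / 2
        lam, w = np.linalg.eigh(sym)
        self._lam = lam                                   # (C, 20)
        self._left = w / sq[:, :, None]                   # (C, 20, 20)
        self._right = np.ascontiguousarray(
            w.transpose(0, 2, 1) * sq[:, None, :])        # (C, 20, 20)
        self._pi = pis
        self._comp_w = model.component_weights()
        if self.per_site_mode:  # one decomposition per alignment column
            self._lam_s = self._lam
            self._left_s = self._left
            self._right_s = self._right
            self._pi_s = self._pi
            # site-major transposed copies for batched matmul
            self._leftT_s = np.ascontiguousarray(
                self._left.transpose(0, 2, 1))
            self._rightT_s = np.ascontiguousarray(
                self._right.transpose(0, 2, 1))

    def set_rates(self, rates: np.ndarray) -> None:
        """Install gamma category rates (mean-1 vector)."""
        rates = np.asarray(rates, dtype=float)
        self.rates = rates
        k = len(rates)
        if self.per_site_mode:
            self.n_combos = k
            self._logw = np.full(k, -np.log(k))
        else:
            ncomp = self._lam.shape[0]
            comp_idx = np.repeat(np.arange(ncomp), k)
            rate_val = np.tile(rates, ncomp)
            self._combo_comp = comp_idx
            self._lam_combo = self._lam[comp_idx] * rate_val[:, None]
            self._left_g = self._left[comp_idx]
            self._right_g = self._right[comp_idx]
            self._rightT_g = np.ascontiguousarray(
                self._right_g.transpose(0, 2, 1))
            self._pi_g = self._pi[comp_idx]
            self.n_combos = ncomp * k
            self._logw = np.log(
                np.repeat(self._comp_w, k) / k)

    # -- elementary operations --------------------------------------------

    def _pmats(self, t: float) -> np.ndarray:
        """(M, 20, 20) transition matrices at edge length t (rates folded)."""
        e = np.exp(self._lam_combo * t)  # (M, 20)
        return np.matmul(self._left_g * e[:, None, :], self._right_g)

    def _contrib(self, v: int, t: float, down, sdown):
        """Child contribution to its parent: (M, npat, 20) plus scale."""
        if self.per_site_mode:
            # into eigenbasis, scale by exp(lam r t), back; batched over sites
            if v < self.flat.n_leaves:
                x = self.leaf_cond[v][:, None, :]  # (s, 1, 20)
            else:
                x = np.ascontiguousarray(down[v].transpose(1, 0, 2))
            tmp = np.matmul(x, self._rightT_s)
            tmp = tmp * np.exp(self._lam_s[:, None, :]
                               * (t * self.rates[None, :, None]))
            out = np.matmul(tmp, self._leftT_s).transpose(1, 0, 2)
            s = 0.0 if v < self.flat.n_leaves else sdown[v]
            return np.ascontiguousarray(out), s
        p = self._pmats(t)
        if v < self.flat.n_leaves:
            return np.matmul(self.leaf_cond[v][None], p.transpose(0, 2, 1)), 0.0
        return np.matmul(down[v], p.transpose(0, 2, 1)), sdown[v]

    @staticmethod
    def _rescale(cond, scale):
        m = np.maximum(cond.max(axis=2), _TINY)
        cond /= m[:, :, None]
        return cond, scale + np.log(m)

    def _combine_children(self, node: int, down, sdown):
        """Product of child contributions, rescaled."""
        cond = None
        scale = np.zeros((self.n_combos, self.n_patterns))
        for v in self.flat.children[node]:
            c, s = self._contrib(v, self.flat.lengths[v], down, sdown)
            cond = c if cond is None else cond * c
            scale += s
        return self._rescale(cond, scale)

    # -- likelihood --------------------------------------------------------

    def _down_pass(self, keep: bool):
        down, sdown = {}, {}
        for node in self.flat.postorder_internal:
            down[node], sdown[node] = self._combine_children(node, down, sdown)
            if not keep:
                for v in self.flat.children[node]:
                    down.pop(v, None)
                    sdown.pop(v, None)
        return down, sdown

    def _root_site_loglik(self, cond_root, scale_root) -> np.ndarray:
        """Per-pattern log-likelihood from root conditionals."""
        if self.per_site_mode:
            like = np.einsum("si,ksi->ks", self._pi_s, cond_root)
        else:
            like = np.einsum("mi,msi->ms", self._pi_g, cond_root)
        loglike = np.log(np.maximum(like, _TINY)) + scale_root
        loglike += self._logw[:, None]
        mx = loglike.max(axis=0)
        return mx + np.log(np.exp(loglike - mx).sum(axis=0))

    def site_loglik(self) -> np.ndarray:
        """Per-pattern log-likelihoods at current branch lengths."""
        down, sdown = self._down_pass(keep=False)
        r = self.flat.root
        return self._root_site_loglik(down[r], sdown[r])

    def loglik(self) -> float:
        return float(self.counts @ self.site_loglik())

    def per_site_loglik(self) -> np.ndarray:
        """Expanded to original site order."""
        return self.site_loglik()[self.pattern_index]

    def component_site_loglik(self) -> np.ndarray:
        """(n_components, n_sites) per-component log-likelihoods
        (gamma-averaged, mixture weights NOT applied)."""
        if self.per_site_mode:
            raise ValueError("component decomposition needs mixture/single mode")
        down, sdown = self._down_pass(keep=False)
        r = self.flat.root
        like = np.einsum("mi,msi->ms", self._pi_g, down[r])
        loglike = np.log(np.maximum(like, _TINY)) + sdown[r]
        k = len(self.rates)
        ncomp = self.n_combos // k
        loglike = loglike.reshape(ncomp, k, -1) - np.log(k)
        mx = loglike.max(axis=1)
        out = mx + np.log(np.exp(loglike - mx[:, None]).sum(axis=1))
        return out[:, self.pattern_index]

    # -- branch-length optimization ----------------------------------------

    def _edge_objective(self, E, sE, v, down, sdown):
        """Fold partials into the eigenbasis for 1-D profiling of edge v."""
        dv = self.leaf_cond[v][None] if v < self.flat.n_leaves else down[v]
        sv = 0.0 if v < self.flat.n_leaves else sdown[v]
        if self.per_site_mode:
            E_s = np.ascontiguousarray(E.transpose(1, 0, 2))
            dv_s = np.ascontiguousarray(dv.transpose(1, 0, 2))
            a = np.matmul(E_s, self._left_s).transpose(1, 0, 2)
            b = np.matmul(dv_s, self._rightT_s).transpose(1, 0, 2)
            lam = self._lam_s[None] * self.rates[:, None, None]  # (k,s,20)
        else:
            a = np.matmul(E, self._left_g)
            b = np.matmul(dv, self._rightT_g)
            lam = self._lam_combo[:, None, :]  # (M,1,20)
        ab = a * b
        scales = sE + sv + self._logw[:, None]
        mx = scales.max(axis=0)
        abw = ab * np.exp(scales - mx)[:, :, None]
        counts = self.counts

        if self.per_site_mode:
            # single-precision is ample for locating the 1-D optimum and
            # halves the cost of the dominant exp/multiply volume
            ns = self.n_patterns
            AB32 = np.ascontiguousarray(
                abw.transpose(1, 0, 2).reshape(ns, -1), dtype=np.float32)
            lam32 = np.ascontiguousarray(
                lam.transpose(1, 0, 2).reshape(ns, -1), dtype=np.float32)

            def neg(t):
                like = np.einsum("sm,sm->s", AB32,
                                 np.exp(lam32 * np.float32(t)))
                return -float(counts @ np.log(np.maximum(
                    like.astype(np.float64), _TINY)))
        else:
            AB = abw.transpose(1, 0, 2).reshape(self.n_patterns, -1)
            lamflat = self._lam_combo.reshape(-1)

            def neg(t):
                like = AB @ np.exp(lamflat * t)
                return -float(counts @ np.log(np.maximum(like, _TINY)))

        return neg, a, sE

    def _edge_up(self, a, sE, t):
        """Up partial for the child node of the just-optimized edge."""
        if self.per_site_mode:
            e = np.exp(self._lam_s[None] * (self.rates[:, None, None] * t))
            ae = np.ascontiguousarray((a * e).transpose(1, 0, 2))
            M = np.ascontiguousarray(
                np.matmul(ae, self._right_s).transpose(1, 0, 2))
        else:
            e = np.exp(self._lam_combo * t)
            M = np.matmul(a * e[:, None, :], self._right_g)
        return self._rescale(M, sE.copy())

    def optimize_branches(self, tol: float = 1e-6, max_cycles: int = 100,
                          bounds=BRANCH_BOUNDS, xatol: float = 1e-5):
        """Coordinate-wise branch optimization; returns (logL, converged, cycles).

        Each cycle visits every edge once in Euler-tour order with exact
        partials, so the total log-likelihood never decreases.
        """
        flat = self.flat
        down, sdown = self._down_pass(keep=True)
        r = flat.root
        prev = float(self.counts @ self._root_site_loglik(down[r], sdown[r]))
        converged = False
        cycle = 0

        if self.per_site_mode:
            pi_root = self._pi_s[None]  # (1, s, 20) broadcasts over rates
        else:
            pi_root = self._pi_g[:, None, :]  # (M, 1, 20)
        zero_scale = np.zeros((self.n_combos, 1))

        for cycle in range(1, max_cycles + 1):
            before = flat.lengths.copy()
            self._tour(r, pi_root, zero_scale, down, sdown, bounds, xatol)
            down[r], sdown[r] = self._combine_children(r, down, sdown)
            cur = float(self.counts @ self._root_site_loglik(down[r], sdown[r]))
            if cur < prev:  # guard against objective round-off
                flat.lengths[:] = before
                converged = True
                break
            if cur - prev < tol:
                prev = cur
                converged = True
                break
            prev = cur
        return prev, converged, cycle

    def _tour(self, u, M_u, sM_u, down, sdown, bounds, xatol):
        flat = self.flat
        kids = flat.children[u]
        for v in kids:
            E, sE_extra = M_u, 0.0
            scale_terms = sM_u
            for s in kids:
                if s is v:
                    continue
                c, sc = self._contrib(s, flat.lengths[s], down, sdown)
                E = E * c
                scale_terms = scale_terms + sc
            E = np.broadcast_to(E, (self.n_combos, self.n_patterns, 20))
            if not E.flags.writeable:
                E = E.copy()
            sE = np.broadcast_to(scale_terms,
                                 (self.n_combos, self.n_patterns)).copy()
            E, sE = self._rescale(E, sE)

            neg, a, sE = self._edge_objective(E, sE, v, down, sdown)
            t0 = flat.lengths[v]
            f0 = neg(t0)
            res = minimize_scalar(neg, bounds=bounds, method="bounded",
                                  options={"xatol": xatol})
            if res.fun < f0:
                flat.lengths[v] = float(res.x)

            if v >= flat.n_leaves:  # internal child: descend, then refresh
                M_v, sM_v = self._edge_up(a, sE, flat.lengths[v])
                self._tour(v, M_v, sM_v, down, sdown, bounds, xatol)
                down[v], sdown[v] = self._combine_children(v, down, sdown)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def log_likelihood(tree: Tree, alignment: Alignment,
                   model: SiteModel) -> LikelihoodResult:
    """Pruning log-likelihood of an alignment on a fixed tree."""
    engine = PruningEngine(tree, alignment, model)
    per_site = engine.per_site_loglik()
    return LikelihoodResult(float(per_site.sum()), per_site, model, tree)


def optimize_branch_lengths(tree: Tree, alignment: Alignment,
                            model: SiteModel, tol: float = 1e-6,
                            max_cycles: int = 100,
                            optimize_alpha: bool = False,
                            alpha_bounds=(0.05, 10.0),
                            alpha_rounds: int = 1,
                            bounds=BRANCH_BOUNDS,
                            xatol: float = 1e-5):
    """ML branch lengths on a fixed topology (optionally with gamma shape).

    The tree is unrooted internally (a bifurcating root is suppressed) and
    returned in that form; non-convergence after ``max_cycles`` is flagged
    on the result, not raised.  With ``optimize_alpha`` the gamma shape is
    interleaved with the branch cycles (``alpha_rounds`` alternations).
    """
    engine = PruningEngine(unroot(tree), alignment, model)
    if optimize_alpha and model.gamma.k > 1:
        total = converged = cycles = None
        for _ in range(max(alpha_rounds, 1)):
            total, converged, cycles = engine.optimize_branches(
                tol, max_cycles, bounds, xatol)
            alpha, total = _alpha_step(engine, model, alpha_bounds)
            model = model.with_alpha(alpha)
        total, converged, cycles = engine.optimize_branches(
            tol, max_cycles, bounds, xatol)
    else:
        total, converged, cycles = engine.optimize_branches(
            tol, max_cycles, bounds, xatol)
    fitted = engine.flat.sync()
    per_site = engine.per_site_loglik()
    result = LikelihoodResult(total, per_site, model, fitted,
                              converged=converged, n_cycles=cycles)
    if not converged:
        # expected under the coarse tolerances used for candidate screening;
        # the result carries the flag for callers that need certainty
        logger.info("branch-length optimization did not converge "
                    "after %d cycles", cycles)
    return fitted, result


def _alpha_step(engine: PruningEngine, model: SiteModel, bounds):
    k = model.gamma.k

    def neg(alpha):
        engine.set_rates(discrete_gamma(float(alpha), k).rates)
        return -engine.loglik()

    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-2})
    best = float(res.x)
    engine.set_rates(discrete_gamma(best, k).rates)
    return best, -res.fun


def estimate_alpha(tree: Tree, alignment: Alignment, model: SiteModel,
                   bounds=(0.05, 10.0)) -> float:
    """ML gamma shape at fixed branch lengths (1-D bounded search)."""
    engine = PruningEngine(tree, alignment, model)
    alpha, _ = _alpha_step(engine, model, bounds)
    return alpha


def pmsf_profiles(alignment: Alignment, guide_tree: Tree,
                  mixture: ProfileMixture,
                  ex: ExchangeabilityMatrix | None = None,
                  gamma: GammaRates | None = None) -> np.ndarray:
    """Posterior mean site frequency profiles on a guide tree.

    For each site the mixture-component posterior is proportional to the
    component weight times the site likelihood under that component; the
    returned (n_sites, 20) profiles are the posterior-weighted averages of
    the component profiles.
    """
    ex = ex or ExchangeabilityMatrix.lg()
    gamma = gamma or discrete_gamma(1.0, 4)
    model = SiteModel(ex, gamma, "mixture", mixture=mixture)
    if mixture.n_components == 1:
        return np.tile(mixture.components[0].probabilities,
                       (alignment.n_sites, 1))
    engine = PruningEngine(guide_tree, alignment, model)
    comp_loglik = engine.component_site_loglik()  # (C, n_sites)
    logpost = comp_loglik + np.log(mixture.weights)[:, None]
    logpost -= logpost.max(axis=0)
    post = np.exp(logpost)
    post /= post.sum(axis=0)
    profiles = post.T @ mixture.profile_matrix()
    return profiles / profiles.sum(axis=1, keepdims=True)


def pmsf_model(alignment: Alignment, guide_tree: Tree,
               mixture: ProfileMixture,
               ex: ExchangeabilityMatrix | None = None,
               gamma: GammaRates | None = None) -> SiteModel:
    """Convenience: per-site SiteModel from :func:`pmsf_profiles`."""
    ex = ex or ExchangeabilityMatrix.lg()
    gamma = gamma or discrete_gamma(1.0, 4)
    profiles = pmsf_profiles(alignment, guide_tree, mixture, ex, gamma)
    return SiteModel.per_site(profiles, ex,
                              alpha=None if gamma.k == 1 else gamma.alpha,
                              k=gamma.k)


def optimize_mixture_weights(tree: Tree, alignment: Alignment,
                             model: SiteModel, n_iter: int = 20,
                             tol: float = 1e-4) -> SiteModel:
    """EM re-estimation of mixture weights at fixed branch lengths."""
    if model.frequency_mode != "mixture":
        return model
    engine = PruningEngine(tree, alignment, model)
    comp_loglik = engine.component_site_loglik()
    w = np.asarray(model.mixture.weights, dtype=float)
    prev = -np.inf
    for _ in range(n_iter):
        logj = comp_loglik + np.log(np.maximum(w, 1e-12))[:, None]
        mx = logj.max(axis=0)
        total = float((mx + np.log(np.exp(logj - mx).sum(axis=0))).sum())
        if total - prev < tol:
            break
        prev = total
        post = np.exp(logj - mx)
        post /= post.sum(axis=0)
        w = post.mean(axis=1)
    mix = model.mixture.reweighted(w)
    return SiteModel(model.exchangeabilities, model.gamma, "mixture",
                     mixture=mix)
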