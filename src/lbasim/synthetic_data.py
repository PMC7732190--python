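"""Synthetic inputs with the statistical structure the analyses assume.

The backbone generator builds a small multi-clade tree emulating the
branch-length regime that makes long-branch attraction a live risk: an
outgroup and a focal clade on long terminal branches, two further ingroup
clades on short terminals, and very short internal branches.  Its two
arrangements differ only in where the focal clade attaches:

* ``farris`` -- the focal clade is sister to the outgroup, so the two long
  branches are truly adjacent and convergent substitutions reinforce the
  true tree (the Farris / inverse-Felsenstein zone);
* ``felsenstein`` -- the focal clade sits inside, sister to a designated
  short-branch clade, so attraction between the long branches pulls
  inference toward the wrong (farris-like) resolution.

Because the two arrangements share an identical branch-length multiset,
any recovery asymmetry between them cannot be a tree-length artifact.

Profile sets are drawn from a symmetric Dirichlet: low concentration
(default 0.2) gives sparse, strongly heterogeneous amino-acid profiles,
the property that drives convergent substitutions under-modeled by
site-homogeneous inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Node, Tree
from .models import FrequencyProfile, ProfileMixture, SiteModel, discrete_gamma
from .simulate import simulate_alignment

ARRANGEMENTS = ("farris", "felsenstein")


@dataclass
class BackboneConfig:
    """Branch-length regime of the synthetic backbone.

    Defaults (12 taxa; long terminals ~1.0-1.2, short terminals 0.25,
    internals 0.04 substitutions/site) are package calibration choices that
    place the felsenstein arrangement firmly in the LBA-sensitive regime.
    """

    n_outgroup: int = 3
    n_focal: int = 3
    ingroup_sizes: tuple[int, ...] = (3, 3)
    outgroup_terminal: float = 1.2
    focal_terminal: float = 1.0
    ingroup_terminal: float = 0.25
    internal: float = 0.04
    arrangement: str = "farris"
    #: optional short terminal for the first focal taxon (a slowly evolving
    #: member of an otherwise long-branched clade); the remaining focal
    #: taxa are then the designated long-branch subclade whose removal the
    #: taxon-trimming experiment studies
    focal_slow_terminal: float | None = None

    def __post_init__(self):
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"arrangement must be one of {ARRANGEMENTS}")
        if len(self.ingroup_sizes) < 2:
            raise ValueError("need at least two ingroup clades")
        sizes = (self.n_outgroup, self.n_focal, *self.ingroup_sizes)
        if any(s < 1 for s in sizes):
            raise ValueError("every clade needs at least one taxon")
        for name in ("outgroup_terminal", "focal_terminal",
                     "ingroup_terminal", "internal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _subtree_leaves(node: Node) -> list[Node]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def _balanced_clade(names: list[str], terminal: float,
                    internal: float) -> Node:
    """Balanced subtree over ``names`` with equal terminal branch lengths."""
    if len(names) == 1:
        return Node(names[0], terminal)
    mid = len(names) // 2
    left = _balanced_clade(names[:mid], terminal, internal)
    right = _balanced_clade(names[mid:], terminal, internal)
    node = Node(None, internal, [left, right])
    return node


def make_backbone(config: BackboneConfig | None = None, seed=None) -> Tree:
    """Backbone tree with named clades; pure function of the config.

    The root is the central trifurcation, so the two arrangements are the
    two possible attachments of the focal clade on an otherwise identical
    unrooted tree.  ``tree.clades`` maps clade names (``outgroup``,
    ``focal``, ``ingroupA``, ``ingroupB``, ...) to leaf sets.
    """
    config = config or BackboneConfig()
    out_names = [f"Out{i+1}" for i in range(config.n_outgroup)]
    foc_names = [f"Foc{i+1}" for i in range(config.n_focal)]
    ing_names = [
        [f"In{chr(ord('A') + j)}{i+1}" for i in range(n)]
        for j, n in enumerate(config.ingroup_sizes)
    ]

    out_sub = _balanced_clade(out_names, config.outgroup_terminal,
                              config.internal)
    out_sub.length = config.internal
    foc_sub = _balanced_clade(foc_names, config.focal_terminal,
                              config.internal)
    foc_sub.length = config.internal
    if config.focal_slow_terminal is not None:
        for leaf in _subtree_leaves(foc_sub):
            if leaf.name == foc_names[0]:
                leaf.length = config.focal_slow_terminal
    ing_subs = []
    for names in ing_names:
        s = _balanced_clade(names, config.ingroup_terminal, config.internal)
        s.length = config.internal
        ing_subs.append(s)

    rest = ing_subs[2:]  # extra ingroup clades ladderize onto the first pair
    a, b = ing_subs[0], ing_subs[1]

    if config.arrangement == "farris":
        # central node joins (outgroup, focal) against the ingroup pair
        pair = Node(None, config.internal, [a, b])
        for extra in rest:
            pair = Node(None, config.internal, [pair, extra])
        root = Node(None, 0.0, [out_sub, foc_sub, pair])
    else:
        # focal tucked inside, sister to ingroup clade B
        inner = Node(None, config.internal, [foc_sub, b])
        for extra in rest:
            inner = Node(None, config.internal, [inner, extra])
        root = Node(None, 0.0, [out_sub, a, inner])

    clades = {
        "outgroup": frozenset(out_names),
        "focal": frozenset(foc_names),
    }
    for j, names in enumerate(ing_names):
        clades[f"ingroup{chr(ord('A') + j)}"] = frozenset(names)
    return Tree(root, clades)


def backbone_pair(config: BackboneConfig | None = None):
    """Paired (farris, felsenstein) trees differing only in attachment."""
    from dataclasses import replace

    config = config or BackboneConfig()
    return (make_backbone(replace(config, arrangement="farris")),
            make_backbone(replace(config, arrangement="felsenstein")))


def make_profile_set(n_components: int, concentration: float = 0.2,
                     seed=0) -> ProfileMixture:
    """Dirichlet-drawn frequency profiles with uniform mixture weights.

    Low concentration yields sparse profiles dominated by few amino acids;
    high concentration approaches the uniform profile.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    comps = []
    for _ in range(n_components):
        p = rng.dirichlet(np.full(20, concentration))
        p = np.maximum(p, 1e-8)
        comps.append(FrequencyProfile(p / p.sum()))
    weights = np.full(n_components, 1.0 / n_components)
    return ProfileMixture(tuple(comps), weights)


_PRESET_PROFILES = {
    # name -> (n_components, concentration, seed)
    "C10-like": (10, 0.2, 101),
    "C60-like": (60, 0.2, 601),
}


def profile_preset(name: str) -> ProfileMixture:
    """Bundled reproducible profile-set presets ("C10-like", "C60-like")."""
    try:
        n, conc, seed = _PRESET_PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; "
                       f"available: {sorted(_PRESET_PROFILES)}") from None
    return make_profile_set(n, conc, seed)


def backbone_preset(name: str) -> Tree:
    """Fixture presets "farris-default" and "felsenstein-default"."""
    if name == "farris-default":
        return make_backbone(BackboneConfig(arrangement="farris"))
    if name == "felsenstein-default":
        return make_backbone(BackboneConfig(arrangement="felsenstein"))
    raise KeyError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# Gene sets with a quality gradient
# ---------------------------------------------------------------------------


@dataclass
class GeneSetConfig:
    """Per-gene branch-scale gradient from best to worst genes.

    Best-end genes shrink terminal branches and stretch internals (the
    regime that resists long-branch attraction); worst-end genes do the
    opposite.  Scales interpolate linearly across the gene list.
    """

    n_genes: int = 20
    sites_per_gene: int = 500
    terminal_scale_range: tuple[float, float] = (0.5, 2.0)
    internal_scale_range: tuple[float, float] = (1.5, 0.5)

    def __post_init__(self):
        if self.n_genes < 1 or self.sites_per_gene < 1:
            raise ValueError("n_genes and sites_per_gene must be positive")

    def terminal_scales(self) -> np.ndarray:
        return np.linspace(*self.terminal_scale_range, self.n_genes)

    def internal_scales(self) -> np.ndarray:
        return np.linspace(*self.internal_scale_range, self.n_genes)


def scale_tree(tree: Tree, terminal_scale: float,
               internal_scale: float) -> Tree:
    """Scale terminal and internal branches by separate factors."""
    t = tree.copy()
    for node in t.postorder():
        if node is t.root:
            continue
        node.length *= terminal_scale if node.is_leaf else internal_scale
    return t


def make_gene_set(backbone: Tree, config: GeneSetConfig | None,
                  gen_model: SiteModel, seed):
    """Simulate genes of graded quality on a backbone.

    Returns a list of ``(Alignment, true_rank)`` with rank 0 the best gene
    (shortest terminals, longest internals), so downstream monophyly
    ranking can be validated against ground truth.
    """
    config = config or GeneSetConfig()
    tscales = config.terminal_scales()
    iscales = config.internal_scales()
    out = []
    for g in range(config.n_genes):
        rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                           spawn_key=(g,)))
        gene_tree = scale_tree(backbone, tscales[g], iscales[g])
        aln, _ = simulate_alignment(gene_tree, gen_model,
                                    config.sites_per_gene, seed=None, rng=rng)
        out.append((aln, g))
    return out


def geneset_preset(seed: int = 7):
    """Fixture preset "geneset-default": graded genes on the farris backbone."""
    backbone = backbone_preset("farris-default")
    mixture = make_profile_set(20, 0.2, seed=seed)
    gen_model = SiteModel.mixture_model(mixture, alpha=0.8)
    return make_gene_set(backbone, GeneSetConfig(), gen_model, seed)
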