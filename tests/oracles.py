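"""Independent reference implementations used as test oracles.

These deliberately avoid the package's pruning machinery: likelihoods are
computed by explicit enumeration of all internal-node state assignments
with `scipy.linalg.expm` transition matrices, so they are slow but
trustworthy on tiny problems.
"""

import itertools

import numpy as np

from lbasim.core import GAP_CODE
from lbasim.models import FrequencyProfile, build_rate_matrix, transition_matrix


def brute_force_site_loglik(tree, alignment, model):
    """Per-site log-likelihood by enumeration over internal states."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    parent = {}
    for n in nodes:
        for c in n.children:
            parent[id(c)] = n
    profs = np.atleast_2d(model.component_profiles())
    weights = np.atleast_1d(model.component_weights())
    rates = model.gamma.rates
    k = len(rates)
    taxon_row = {t: i for i, t in enumerate(alignment.taxa)}

    out = []
    for s in range(alignment.n_sites):
        site_like = 0.0
        for c in range(len(profs)):
            prof = FrequencyProfile(profs[c] / profs[c].sum())
            q = build_rate_matrix(model.exchangeabilities, prof)
            pi = prof.clamped()
            for r in rates:
                pmats = {
                    id(n): transition_matrix(q, n.length * r)
                    for n in nodes if n is not tree.root
                }
                total = 0.0
                for assign in itertools.product(range(20),
                                                repeat=len(internals)):
                    state = {id(n): a for n, a in zip(internals, assign)}
                    p = pi[state[id(tree.root)]]
                    for n in nodes:
                        if n is tree.root:
                            continue
                        ps = state[id(parent[id(n)])]
                        if n.is_leaf:
                            obs = alignment.data[taxon_row[n.name], s]
                            p *= 1.0 if obs == GAP_CODE else pmats[id(n)][ps, obs]
                        else:
                            p *= pmats[id(n)][ps, state[id(n)]]
                    total += p
                site_like += weights[c] / k * total
        out.append(np.log(site_like))
    return np.array(out)
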