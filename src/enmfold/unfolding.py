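"""Iterative-GNM unfolding simulation.

Thermal unfolding is mimicked by repeatedly removing the currently
"weakest" native contact from a backbone-weighted GNM.  Interactions
split into covalent springs (chain-adjacent pairs, strength c*gamma,
never removed) and non-covalent contacts (all other pairs within the
GNM cutoff, strength gamma).  Each step:

1. build the Kirchhoff matrix of the current topology,
2. compute the mean-square distance fluctuation of every surviving
   contact, <dR_ij^2> = <dR_i^2> + <dR_j^2> - 2 <dR_i.dR_j>,
3. break one contact chosen uniformly among the ``noise_top_k`` largest
   fluctuations (top-1 makes the walk deterministic),

until no non-covalent contact remains.  The number of native
non-covalent contacts lost so far (LNNC) is the unfolding progress
coordinate.  Replicate ensembles give per-domain unfolding curves,
contact-map snapshots at fixed LNNC, and "weak regions": spatial
clusters of contacts that break within the first ~20% of steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .enm_core import Covariance, ENMParams, KirchhoffMatrix, pseudo_inverse
from .structure_io import CaModel, DomainMap, assign_domains

__all__ = [
    "IterativeENMParams",
    "ContactTopology",
    "UnfoldingTrajectory",
    "UnfoldingCurves",
    "WeakRegionReport",
    "WeakRegion",
    "native_topology",
    "fit_backbone_factor",
    "build_iterative_kirchhoff",
    "distance_fluctuations",
    "unfold_step",
    "run_unfolding",
    "unfolding_curves",
    "contact_map_snapshot",
    "weak_regions",
    "mean_break_steps",
]


@dataclass(frozen=True)
class IterativeENMParams:
    """Parameters of the backbone-weighted iterative GNM.

    ``backbone_factor`` is the multiplier c giving covalent springs
    strength c*gamma; it is meant to be fit against crystallographic
    B-factors (default 10).  ``noise_top_k`` contacts compete for
    rupture each step (default 3, modelling thermal noise); the run is
    repeated ``replicates`` times from ``seed``.
    """

    enm: ENMParams = field(default_factory=ENMParams)
    backbone_factor: float = 10.0
    noise_top_k: int = 3
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.backbone_factor < 1:
            raise ValueError("backbone_factor must be >= 1")
        if self.noise_top_k < 1 or self.replicates < 1:
            raise ValueError("noise_top_k and replicates must be >= 1")


@dataclass
class ContactTopology:
    """Mutable contact state of one unfolding run.

    ``covalent`` (chain-adjacent pairs, immutable) and ``noncovalent``
    are sets of 0-based (i, j) with i < j; ``native_distances`` maps
    every native pair to its native CA separation in A.  ``lnnc`` is the
    count of removed native non-covalent contacts.
    """

    n: int
    covalent: frozenset
    noncovalent: set
    native_distances: dict
    native_noncovalent_count: int

    @property
    def lnnc(self) -> int:
        return self.native_noncovalent_count - len(self.noncovalent)

    def copy(self) -> "ContactTopology":
        return ContactTopology(
            n=self.n,
            covalent=self.covalent,
            noncovalent=set(self.noncovalent),
            native_distances=self.native_distances,
            native_noncovalent_count=self.native_noncovalent_count,
        )


def native_topology(model: CaModel, params: IterativeENMParams | None = None) -> ContactTopology:
    """Native contact topology of a CA model.

    Chain-adjacent pairs (minus chain breaks) are covalent regardless of
    distance; every other pair within the GNM cutoff is a non-covalent
    native contact.
    """
    params = params or IterativeENMParams()
    coords = model.coords
    n = len(coords)
    d = squareform(pdist(coords))
    covalent = frozenset((i, j) for i, j in model.covalent_pairs())
    ii, jj = np.nonzero(np.triu(d <= params.enm.cutoff_gnm, k=1))
    noncov = {
        (int(i), int(j)) for i, j in zip(ii, jj) if (int(i), int(j)) not in covalent
    }
    native_d = {p: float(d[p]) for p in covalent | noncov}
    return ContactTopology(
        n=n,
        covalent=covalent,
        noncovalent=noncov,
        native_distances=native_d,
        native_noncovalent_count=len(noncov),
    )


def fit_backbone_factor(
    model: CaModel, grid=(2.0, 5.0, 10.0, 20.0, 50.0)
) -> tuple:
    """Pick the backbone factor c maximizing B-factor correlation.

    For each candidate c, builds the backbone-weighted native Kirchhoff
    matrix and scores the Pearson correlation between predicted and
    experimental B-factors; returns ``(best_c, {c: r})``.  Requires
    non-constant experimental B-factors.
    """
    from scipy.stats import pearsonr

    b_exp = model.bfactors
    if np.allclose(b_exp, b_exp[0]):
        raise ValueError("experimental B-factors are constant; fit is degenerate")
    scores = {}
    for c in grid:
        params = IterativeENMParams(backbone_factor=float(c))
        topo = native_topology(model, params)
        k = build_iterative_kirchhoff(topo, params)
        _, cov = pseudo_inverse(k, strict=False)
        scores[float(c)] = float(pearsonr(np.diag(cov.matrix), b_exp)[0])
    best = max(scores, key=scores.get)
    return best, scores


def build_iterative_kirchhoff(
    topology: ContactTopology, params: IterativeENMParams
) -> KirchhoffMatrix:
    """Backbone-weighted Kirchhoff matrix of the current topology.

    Off-diagonal entries: -c*gamma for covalent pairs, -gamma for
    surviving non-covalent contacts; diagonal balances rows.
    """
    gamma = params.enm.gamma
    n = topology.n
    k = np.zeros((n, n))
    for i, j in topology.covalent:
        k[i, j] = k[j, i] = -params.backbone_factor * gamma
    for i, j in topology.noncovalent:
        k[i, j] = k[j, i] = -gamma
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, -k.sum(axis=1))
    return KirchhoffMatrix(
        matrix=k,
        params=params.enm,
        contact_list=sorted(topology.covalent | topology.noncovalent),
    )


def distance_fluctuations(cov: Covariance, topology: ContactTopology) -> dict:
    """Mean-square distance fluctuation of every current contact.

    <dR_ij^2> = <dR_i^2> + <dR_j^2> - 2 <dR_i.dR_j>, from the covariance
    of the current topology's matrix.  Returns {(i, j): value}.
    """
    m = cov.matrix
    diag = np.diag(m)
    out = {}
    for i, j in topology.covalent | topology.noncovalent:
        val = float(diag[i] + diag[j] - 2.0 * m[i, j])
        if val < -1e-10:
            raise ValueError(f"negative distance fluctuation at {(i, j)}: {val}")
        out[(i, j)] = max(val, 0.0)
    return out


def _ranked_noncovalent(fluct: dict, topology: ContactTopology):
    """Non-covalent contacts by (fluctuation desc, i asc, j asc)."""
    items = [(p, fluct[p]) for p in topology.noncovalent]
    items.sort(key=lambda t: (-t[1], t[0][0], t[0][1]))
    return items


def unfold_step(topology: ContactTopology, params: IterativeENMParams, rng):
    """Break one contact; return (new_topology, broken_pair, fluctuation).

    Ranks current non-covalent contacts by distance fluctuation and
    removes one chosen uniformly among the top ``noise_top_k``
    (deterministically the arg-max when k=1).  Covalent springs are
    never broken.  Tie-breaking is stable by (fluctuation desc, i, j)
    for bit-reproducibility.
    """
    if not topology.noncovalent:
        raise RuntimeError("unfolding already terminated: no non-covalent contacts")
    k = build_iterative_kirchhoff(topology, params)
    # late-stage topologies may fragment across chain breaks: tolerate
    # extra zero modes per component
    _, cov = pseudo_inverse(k, strict=False)
    fluct = distance_fluctuations(cov, topology)
    ranked = _ranked_noncovalent(fluct, topology)
    top = ranked[: min(params.noise_top_k, len(ranked))]
    if len(top) == 1 or params.noise_top_k == 1:
        pair, value = top[0]
    else:
        pair, value = top[int(rng.integers(len(top)))]
    new_topo = topology.copy()
    new_topo.noncovalent.discard(pair)
    return new_topo, pair, value


@dataclass
class UnfoldingTrajectory:
    """Ordered record of broken contacts for one seeded replicate."""

    replicate_id: int
    seed: int
    events: list  # (step starting at 1, (i, j), fluctuation at break)
    terminal: bool = True

    @property
    def break_step(self) -> dict:
        return {pair: step for step, pair, _val in self.events}


def run_unfolding(
    model: CaModel, params: IterativeENMParams | None = None, progress=None
) -> list:
    """Unfold a model ``params.replicates`` times.

    Replicate r uses an independent generator seeded ``seed + r``, so a
    fixed master seed reproduces every event list bit-for-bit.  Each
    replicate runs until all non-covalent contacts are broken.
    """
    params = params or IterativeENMParams()
    topo0 = native_topology(model, params)
    trajectories = []
    for r in range(params.replicates):
        rep_seed = params.seed + r
        rng = np.random.default_rng(rep_seed)
        topo = topo0.copy()
        events = []
        step = 0
        while topo.noncovalent:
            step += 1
            topo, pair, value = unfold_step(topo, params, rng)
            events.append((step, pair, value))
            if progress is not None:
                progress(r, step)
        trajectories.append(
            UnfoldingTrajectory(replicate_id=r, seed=rep_seed, events=events)
        )
    return trajectories


def _contact_domain_class(pair, labels, domain_map: DomainMap):
    i, j = pair
    a = domain_map.composite_label(labels[i])
    b = domain_map.composite_label(labels[j])
    return (a, None) if a == b else (a, b)


@dataclass
class UnfoldingCurves:
    """Replicate-averaged surviving-contact fractions per domain.

    ``intra[label]`` and ``inter[label]`` are arrays over the shared
    step axis 0..n_steps; ``intra_sd``/``inter_sd`` hold the replicate
    standard deviation.  ``inter`` counts contacts between the labeled
    (composite) domain and any other domain.
    """

    steps: np.ndarray
    intra: dict
    inter: dict
    intra_sd: dict
    inter_sd: dict
    native_intra_counts: dict
    native_inter_counts: dict


def unfolding_curves(
    trajectories, topology0: ContactTopology, model: CaModel, domain_map: DomainMap
) -> UnfoldingCurves:
    """Per-domain intra/inter surviving-contact fraction curves.

    A native non-covalent contact is intra-domain when both residues
    share a composite domain label, else it is inter-domain for both
    domains involved.  Per-replicate step functions are averaged.
    """
    labels = assign_domains(model, domain_map)
    comp = [domain_map.composite_label(l) for l in labels]
    domains = sorted(set(comp))
    native = sorted(topology0.noncovalent)
    intra_members = {d: [] for d in domains}
    inter_members = {d: [] for d in domains}
    for pair in native:
        a, b = comp[pair[0]], comp[pair[1]]
        if a == b:
            intra_members[a].append(pair)
        else:
            inter_members[a].append(pair)
            inter_members[b].append(pair)
    n_steps = max(len(t.events) for t in trajectories)
    steps = np.arange(n_steps + 1)

    def curves_for(members):
        out, out_sd = {}, {}
        for d in domains:
            pairs = members[d]
            if not pairs:
                out[d] = np.full(n_steps + 1, np.nan)
                out_sd[d] = np.full(n_steps + 1, np.nan)
                continue
            per_rep = np.ones((len(trajectories), n_steps + 1))
            for r, t in enumerate(trajectories):
                bs = t.break_step
                surv = np.full(n_steps + 1, len(pairs), dtype=float)
                for p in pairs:
                    s = bs.get(p)
                    if s is not None:
                        surv[s:] -= 1
                per_rep[r] = surv / len(pairs)
            out[d] = per_rep.mean(axis=0)
            out_sd[d] = per_rep.std(axis=0)
        return out, out_sd

    intra, intra_sd = curves_for(intra_members)
    inter, inter_sd = curves_for(inter_members)
    return UnfoldingCurves(
        steps=steps,
        intra=intra,
        inter=inter,
        intra_sd=intra_sd,
        inter_sd=inter_sd,
        native_intra_counts={d: len(v) for d, v in intra_members.items()},
        native_inter_counts={d: len(v) for d, v in inter_members.items()},
    )


def pair_survival_curve(trajectories, pairs, n_steps=None) -> np.ndarray:
    """Replicate-mean surviving fraction of an arbitrary contact set."""
    pairs = list(pairs)
    if n_steps is None:
        n_steps = max(len(t.events) for t in trajectories)
    per_rep = np.ones((len(trajectories), n_steps + 1))
    for r, t in enumerate(trajectories):
        bs = t.break_step
        surv = np.full(n_steps + 1, float(len(pairs)))
        for p in pairs:
            s = bs.get(p)
            if s is not None and s <= n_steps:
                surv[s:] -= 1
        per_rep[r] = surv / len(pairs)
    return per_rep.mean(axis=0)


def contact_map_snapshot(trajectories, topology0: ContactTopology, lnnc_value: int) -> np.ndarray:
    """Mean contact-presence matrix at a fixed LNNC.

    For each replicate, take the topology right after the
    ``lnnc_value``-th rupture (native topology for 0) and average the
    0/1 presence of every native non-covalent contact.  Covalent pairs
    are always present.
    """
    if not 0 <= lnnc_value <= topology0.native_noncovalent_count:
        raise ValueError("lnnc_value out of range")
    n = topology0.n
    acc = np.zeros((n, n))
    for t in trajectories:
        broken = {pair for step, pair, _ in t.events[:lnnc_value]}
        for pair in topology0.noncovalent:
            if pair not in broken:
                acc[pair] += 1.0
                acc[pair[1], pair[0]] += 1.0
    acc /= len(trajectories)
    for pair in topology0.covalent:
        acc[pair] = acc[pair[1], pair[0]] = 1.0
    return acc


def mean_break_steps(trajectories, topology0: ContactTopology) -> dict:
    """Replicate-mean break step of every native non-covalent contact."""
    sums = {p: 0.0 for p in topology0.noncovalent}
    for t in trajectories:
        bs = t.break_step
        for p in sums:
            sums[p] += bs[p]
    return {p: s / len(trajectories) for p, s in sums.items()}


@dataclass
class WeakRegion:
    cluster_id: int
    pairs: list                 # residue index pairs (0-based)
    mean_break_step: float      # averaged over member contacts
    center: np.ndarray          # geometric center of contact midpoints, A
    domains: tuple              # sorted involved composite domain labels


@dataclass
class WeakRegionReport:
    threshold: int
    regions: list


def weak_regions(
    trajectories,
    topology0: ContactTopology,
    coords: np.ndarray,
    step_threshold: int = 500,
    model: CaModel | None = None,
    domain_map: DomainMap | None = None,
    cluster_cutoff: float = 10.0,
) -> WeakRegionReport:
    """Cluster early-breaking contacts into spatial weak regions.

    A contact is weak when its replicate-mean break step is <=
    ``step_threshold`` (the first ~20% of steps in the full-size
    setting).  Weak contacts are single-linkage clustered on their
    native midpoint positions with a ``cluster_cutoff`` (A) criterion;
    each cluster is reported with its geometric center, mean break step
    and involved domains.
    """
    mean_steps = mean_break_steps(trajectories, topology0)
    weak = [(p, s) for p, s in sorted(mean_steps.items()) if s <= step_threshold]
    if not weak:
        return WeakRegionReport(threshold=step_threshold, regions=[])
    mids = np.array([(coords[p[0]] + coords[p[1]]) / 2.0 for p, _ in weak])
    if len(weak) == 1:
        labels = np.array([1])
    else:
        z = linkage(mids, method="single")
        labels = fcluster(z, t=cluster_cutoff, criterion="distance")
    comp = None
    if model is not None and domain_map is not None:
        per_res = assign_domains(model, domain_map)
        comp = [domain_map.composite_label(l) for l in per_res]
    regions = []
    for cid in sorted(set(labels)):
        idx = [k for k, l in enumerate(labels) if l == cid]
        pairs = [weak[k][0] for k in idx]
        steps = [weak[k][1] for k in idx]
        involved = ()
        if comp is not None:
            involved = tuple(sorted({comp[i] for p in pairs for i in p}))
        regions.append(
            WeakRegion(
                cluster_id=int(cid),
                pairs=pairs,
                mean_break_step=float(np.mean(steps)),
                center=mids[idx].mean(axis=0),
                domains=involved,
            )
        )
    regions.sort(key=lambda r: r.mean_break_step)
    return WeakRegionReport(threshold=step_threshold, regions=regions)
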