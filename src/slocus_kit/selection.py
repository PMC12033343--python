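"""Codon substitution models and likelihood-ratio tests for positive
diversifying selection.

Implements the Goldman-Yang/Muse-Gaut style 61-state Markov model family
used for dN/dS inference:

* ``M0`` — one ratio: a single omega for every branch and site;
* ``branch_2ratio`` — separate omega for labelled foreground branches
  (``#1`` in the Newick) and background branches;
* ``branchsite_A_null`` / ``branchsite_A_alt`` — branch-site model A with
  four site classes (0, 1, 2a, 2b) and foreground omega2 fixed at 1 (null)
  or free >= 1 (alternative).

Likelihoods are computed by Felsenstein pruning over codon states with
per-node rescaling; transition matrices come from the eigendecomposition
of the pi-symmetrised generator (the model is time-reversible).  Fitting
maximises the log-likelihood with L-BFGS-B over log/logistic-transformed
parameters, multi-start.  The same transition matrices drive the
simulator used by :mod:`slocus_kit.synthetic_data`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .codons import (
    CODON_INDEX,
    GENETIC_CODE,
    N_SENSE,
    SENSE_CODONS,
    is_transition,
)

# ---------------------------------------------------------------------------
# static codon-pair classification

_N_PAIRS: list[tuple[int, int, bool, bool]] = []  # i, j, is_ts, is_syn
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diff = [k for k in range(3) if _ci[k] != _cj[k]]
        if len(diff) != 1:
            continue
        k = diff[0]
        _N_PAIRS.append(
            (_i, _j, is_transition(_ci[k], _cj[k]), GENETIC_CODE[_ci] == GENETIC_CODE[_cj])
        )
_PAIR_I = np.array([p[0] for p in _N_PAIRS])
_PAIR_J = np.array([p[1] for p in _N_PAIRS])
_PAIR_TS = np.array([p[2] for p in _N_PAIRS])
_PAIR_SYN = np.array([p[3] for p in _N_PAIRS])


def codon_rate_matrix(kappa: float, omega: float, codon_freqs: np.ndarray) -> np.ndarray:
    """61x61 generator: q_ij = pi_j * {1, kappa, omega, kappa*omega} for
    single-nucleotide {syn tv, syn ts, nonsyn tv, nonsyn ts} changes, zero
    for multi-step changes; scaled to one expected substitution per codon
    per unit branch length."""
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_SENSE,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("codon_freqs must be 61 non-negative values summing to 1")
    rates = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    Q = np.zeros((N_SENSE, N_SENSE))
    Q[_PAIR_I, _PAIR_J] = rates * pi[_PAIR_J]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


class _TransitionCache:
    """Eigendecomposition-backed P(t) for one (kappa, omega, pi)."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        Q = codon_rate_matrix(kappa, omega, pi)
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]  # D^{-1/2} V
        self._right = (evecs * sqrt_pi[:, None]).T  # V^T D^{1/2}

    def P(self, t: float) -> np.ndarray:
        if t == 0:
            return np.eye(N_SENSE)
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# alignment & tree containers


@dataclass
class CodonAlignment:
    taxa: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("need >= 2 taxa")
        if len({len(s) for s in self.seqs}) != 1:
            raise ValueError("sequences of unequal length")
        L = len(self.seqs[0])
        if L % 3 != 0 or L == 0:
            raise ValueError("alignment length must be a positive multiple of 3")
        self.seqs = [s.upper() for s in self.seqs]
        for tax, s in zip(self.taxa, self.seqs):
            for i in range(0, L, 3):
                if s[i : i + 3] not in CODON_INDEX:
                    raise ValueError(
                        f"non-sense codon {s[i:i+3]!r} in {tax} at codon {i // 3}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def codon_codes(self) -> np.ndarray:
        """(n_taxa, n_codons) int matrix of sense-codon state indices."""
        return np.array(
            [
                [CODON_INDEX[s[i : i + 3]] for i in range(0, len(s), 3)]
                for s in self.seqs
            ],
            dtype=np.int32,
        )

    def f3x4_frequencies(self) -> np.ndarray:
        """F3x4 equilibrium codon frequencies: positional nucleotide
        frequencies multiplied, renormalised over the 61 sense codons."""
        pos = np.zeros((3, 4))
        order = "TCAG"
        for s in self.seqs:
            for i, c in enumerate(s):
                pos[i % 3, order.index(c)] += 1
        pos /= pos.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                pos[0, order.index(c[0])]
                * pos[1, order.index(c[1])]
                * pos[2, order.index(c[2])]
                for c in SENSE_CODONS
            ]
        )
        return pi / pi.sum()


@dataclass
class _Node:
    index: int
    parent: int  # -1 for root
    length: float
    foreground: bool
    taxon: str | None  # None for internal


@dataclass
class LabeledTree:
    """Rooted-representation tree with optional foreground branch marks.

    Branches are marked foreground by a ``#1`` suffix on the corresponding
    node label in the Newick (leaf or internal).  Likelihood under a
    reversible model is invariant to the rooting.
    """

    nodes: list[_Node]  # postorder; root last
    newick: str = ""

    @classmethod
    def from_newick(cls, newick: str) -> "LabeledTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        nodes: list[_Node] = []
        index_of: dict[int, int] = {}
        for nd in tree.postorder_node_iter():
            label = nd.taxon.label if nd.taxon else (nd.label or "")
            fg = label.endswith("#1")
            if fg:
                label = label[:-2].strip()
            nodes.append(
                _Node(
                    index=len(nodes),
                    parent=-1,
                    length=float(nd.edge.length or 0.0),
                    foreground=fg,
                    taxon=label if nd.is_leaf() else None,
                )
            )
            index_of[id(nd)] = len(nodes) - 1
        for nd in tree.postorder_node_iter():
            if nd.parent_node is not None:
                nodes[index_of[id(nd)]].parent = index_of[id(nd.parent_node)]
        return cls(nodes, newick=newick.strip())

    @property
    def leaves(self) -> list[_Node]:
        return [n for n in self.nodes if n.taxon is not None]

    @property
    def has_foreground(self) -> bool:
        return any(n.foreground for n in self.nodes[:-1])

    def scaled(self, factor: float) -> "LabeledTree":
        out = LabeledTree(
            [replace(n, length=n.length * factor) for n in self.nodes], self.newick
        )
        return out


# ---------------------------------------------------------------------------
# model specs


@dataclass
class CodonModelSpec:
    model: str  # M0 | branch_2ratio | branchsite_A_null | branchsite_A_alt
    codon_freqs: str = "F3x4"  # F3x4 | equal

    VALID = ("M0", "branch_2ratio", "branchsite_A_null", "branchsite_A_alt")

    def __post_init__(self) -> None:
        if self.model not in self.VALID:
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def needs_foreground(self) -> bool:
        return self.model != "M0"

    @property
    def n_free_params(self) -> int:
        return {
            "M0": 2,
            "branch_2ratio": 3,
            "branchsite_A_null": 4,
            "branchsite_A_alt": 5,
        }[self.model]


def branchsite_class_proportions(p0: float, p1: float) -> np.ndarray:
    """Proportions of site classes (0, 1, 2a, 2b) in branch-site model A."""
    if p0 < 0 or p1 < 0 or p0 + p1 > 1 or p0 + p1 <= 0:
        raise ValueError("need p0, p1 >= 0 with 0 < p0 + p1 <= 1")
    rest = 1.0 - p0 - p1
    p2a = rest * p0 / (p0 + p1)
    p2b = rest * p1 / (p0 + p1)
    props = np.array([p0, p1, p2a, p2b])
    assert np.isclose(props.sum(), 1.0)
    return props


def _site_class_omegas(spec: CodonModelSpec, params: dict) -> list[tuple[float, float, float]]:
    """Per site class: (proportion, omega_background, omega_foreground)."""
    m = spec.model
    if m == "M0":
        w = params["omega"]
        return [(1.0, w, w)]
    if m == "branch_2ratio":
        return [(1.0, params["omega_bg"], params["omega_fg"])]
    w0 = params["omega0"]
    w2 = 1.0 if m == "branchsite_A_null" else params["omega2"]
    props = branchsite_class_proportions(params["p0"], params["p1"])
    return [
        (props[0], w0, w0),
        (props[1], 1.0, 1.0),
        (props[2], w0, w2),
        (props[3], 1.0, w2),
    ]


# ---------------------------------------------------------------------------
# likelihood


def _pattern_compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _prune_site_likelihoods(
    patterns: np.ndarray,
    taxon_row: dict[str, int],
    tree: LabeledTree,
    P_of_branch: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional likelihoods at the root for each site pattern.

    Returns (root_partials (61, npat), log_scale (npat,)).
    """
    npat = patterns.shape[1]
    partial: dict[int, np.ndarray] = {}
    log_scale = np.zeros(npat)
    children: dict[int, list[int]] = {}
    for n in tree.nodes[:-1]:
        children.setdefault(n.parent, []).append(n.index)
    for n in tree.nodes:
        if n.taxon is not None:
            continue
        prod = np.ones((N_SENSE, npat))
        for ci in children.get(n.index, []):
            c = tree.nodes[ci]
            P = P_of_branch[ci]
            if c.taxon is not None:
                msg = P[:, patterns[taxon_row[c.taxon]]]
            else:
                msg = P @ partial.pop(ci)
            prod *= msg
        mx = prod.max(axis=0)
        if np.any(mx <= 0):
            bad = int(np.argmax(mx <= 0))
            raise FloatingPointError(f"zero likelihood at site pattern {bad}")
        prod /= mx
        log_scale += np.log(mx)
        partial[n.index] = prod
    root = tree.nodes[-1].index
    return partial[root], log_scale


def tree_loglikelihood(
    alignment: CodonAlignment,
    tree: LabeledTree,
    spec: CodonModelSpec,
    params: dict,
    codon_freqs: np.ndarray | None = None,
) -> float:
    """Log-likelihood of the alignment by Felsenstein pruning.

    ``params`` holds kappa plus the model's omega set (and p0/p1 for
    branch-site models).  For branch-site models the per-site likelihood is
    the proportion-weighted mixture over site classes.
    """
    if spec.needs_foreground and not tree.has_foreground:
        raise ValueError(f"model {spec.model} requires a foreground (#1) branch mark")
    pi = _resolve_freqs(alignment, spec, codon_freqs)
    codes = alignment.codon_codes()
    patterns, counts = _pattern_compress(codes)
    taxon_row = {t: i for i, t in enumerate(alignment.taxa)}
    for leaf in tree.leaves:
        if leaf.taxon not in taxon_row:
            raise ValueError(f"tree leaf {leaf.taxon!r} not in alignment")

    classes = _site_class_omegas(spec, params)
    kappa = params["kappa"]
    cache: dict[float, _TransitionCache] = {}

    def trans(omega: float) -> _TransitionCache:
        if omega not in cache:
            cache[omega] = _TransitionCache(kappa, omega, pi)
        return cache[omega]

    site_like = np.zeros(patterns.shape[1])
    log_offset: np.ndarray | None = None
    per_class: list[tuple[float, np.ndarray, np.ndarray]] = []
    for prop, w_bg, w_fg in classes:
        P_of_branch: list[np.ndarray] = []
        for n in tree.nodes:
            if n.parent == -1:
                P_of_branch.append(np.eye(N_SENSE))
                continue
            w = w_fg if n.foreground else w_bg
            P_of_branch.append(trans(w).P(n.length))
        root_partial, log_scale = _prune_site_likelihoods(
            patterns, taxon_row, tree, P_of_branch
        )
        L = pi @ root_partial
        per_class.append((prop, L, log_scale))
    log_offset = np.max([ls for _, _, ls in per_class], axis=0)
    for prop, L, log_scale in per_class:
        site_like += prop * L * np.exp(log_scale - log_offset)
    if np.any(site_like <= 0):
        bad = int(np.argmax(site_like <= 0))
        raise FloatingPointError(f"non-positive site likelihood at pattern {bad}")
    ll = float(np.dot(counts, np.log(site_like) + log_offset))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    return ll


def _resolve_freqs(
    alignment: CodonAlignment, spec: CodonModelSpec, codon_freqs: np.ndarray | None
) -> np.ndarray:
    if codon_freqs is not None:
        pi = np.asarray(codon_freqs, dtype=float)
    elif spec.codon_freqs == "equal":
        pi = np.full(N_SENSE, 1.0 / N_SENSE)
    elif spec.codon_freqs == "F3x4":
        pi = alignment.f3x4_frequencies()
    else:
        raise ValueError(f"unknown codon_freqs mode {spec.codon_freqs!r}")
    observed = set(np.unique(alignment.codon_codes()))
    zero = [SENSE_CODONS[i] for i in observed if pi[i] == 0]
    if zero:
        raise ValueError(f"zero equilibrium frequency on observed codon(s) {zero}")
    return pi


# ---------------------------------------------------------------------------
# fitting


@dataclass
class CodonModelFit:
    spec: CodonModelSpec
    params: dict
    loglik: float
    converged: bool
    n_iterations: int
    n_starts: int = 1


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


class _ParamCodec:
    """Map model parameters to/from an unconstrained optimisation vector.

    kappa and omegas are log-transformed (omega2 of the alternative
    branch-site model is offset so omega2 >= 1); the site-class
    proportions use a nested logistic transform.
    """

    def __init__(self, spec: CodonModelSpec):
        self.spec = spec

    def encode(self, params: dict) -> np.ndarray:
        m = self.spec.model
        x = [np.log(params["kappa"])]
        if m == "M0":
            x.append(np.log(params["omega"]))
        elif m == "branch_2ratio":
            x += [np.log(params["omega_bg"]), np.log(params["omega_fg"])]
        else:
            x += [np.log(params["omega0"])]
            s = params["p0"] + params["p1"]
            x += [_logit(s), _logit(params["p0"] / s)]
            if m == "branchsite_A_alt":
                x.append(np.log(params["omega2"] - 1.0 + 1e-6))
        return np.array(x)

    def decode(self, x: np.ndarray) -> dict:
        m = self.spec.model
        out = {"kappa": float(np.exp(np.clip(x[0], np.log(0.01), np.log(100))))}
        clip_w = lambda v: float(np.exp(np.clip(v, np.log(1e-4), np.log(50))))
        if m == "M0":
            out["omega"] = clip_w(x[1])
        elif m == "branch_2ratio":
            out["omega_bg"] = clip_w(x[1])
            out["omega_fg"] = clip_w(x[2])
        else:
            out["omega0"] = clip_w(x[1])
            s = _logistic(float(np.clip(x[2], -12, 12)))
            r = _logistic(float(np.clip(x[3], -12, 12)))
            out["p0"] = s * r
            out["p1"] = s * (1 - r)
            if m == "branchsite_A_alt":
                out["omega2"] = 1.0 + float(
                    np.exp(np.clip(x[4], np.log(1e-6), np.log(49)))
                )
        return out


def _default_starts(spec: CodonModelSpec, rng: np.random.Generator, n: int) -> list[dict]:
    starts = []
    for k in range(n):
        if k == 0:
            kappa, w = 2.0, 0.4
        else:
            kappa = float(rng.uniform(0.5, 5.0))
            w = float(rng.uniform(0.05, 2.0))
        m = spec.model
        if m == "M0":
            starts.append({"kappa": kappa, "omega": w})
        elif m == "branch_2ratio":
            starts.append({"kappa": kappa, "omega_bg": w, "omega_fg": w * 1.5})
        elif m == "branchsite_A_null":
            starts.append({"kappa": kappa, "omega0": min(w, 0.9), "p0": 0.6, "p1": 0.3})
        else:
            starts.append(
                {"kappa": kappa, "omega0": min(w, 0.9), "p0": 0.6, "p1": 0.3, "omega2": 2.0}
            )
    return starts


def fit_model(
    alignment: CodonAlignment,
    tree: LabeledTree,
    spec: CodonModelSpec,
    *,
    n_starts: int = 3,
    seed: int = 0,
    codon_freqs: np.ndarray | None = None,
    maxiter: int = 300,
) -> CodonModelFit:
    """Maximum-likelihood fit of a codon model with branch lengths fixed to
    the input tree.  Multi-start L-BFGS-B on transformed parameters; the
    best start is kept.  Deterministic for a given seed."""
    if spec.needs_foreground and not tree.has_foreground:
        raise ValueError(f"model {spec.model} requires a foreground (#1) branch mark")
    pi = _resolve_freqs(alignment, spec, codon_freqs)
    codec = _ParamCodec(spec)
    rng = np.random.default_rng(seed)

    def neg_ll(x: np.ndarray) -> float:
        try:
            return -tree_loglikelihood(alignment, tree, spec, codec.decode(x), pi)
        except FloatingPointError:
            return 1e12

    best: tuple[float, dict, bool, int] | None = None
    for start in _default_starts(spec, rng, n_starts):
        res = optimize.minimize(
            neg_ll,
            codec.encode(start),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        cand = (-res.fun, codec.decode(res.x), bool(res.success), int(res.nit))
        if best is None or cand[0] > best[0]:
            best = cand
    ll, params, ok, nit = best
    return CodonModelFit(
        spec=spec,
        params=params,
        loglik=float(ll),
        converged=ok,
        n_iterations=nit,
        n_starts=n_starts,
    )


@dataclass
class LRTResult:
    two_delta_l: float
    df: int
    p_value: float
    reject_at_5pct: bool


def lrt(loglik_null: float, loglik_alt: float, df: int = 1) -> LRTResult:
    """Likelihood-ratio test of nested codon models against chi^2_df.

    A (numerically) negative 2*delta-l is clamped to zero with a warning.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    raw = 2.0 * (loglik_alt - loglik_null)
    if raw < 0:
        import warnings

        if raw < -1e-6:
            warnings.warn(f"negative 2*delta-l ({raw:.3g}) clamped to 0")
        raw = 0.0
    p = float(chi2.sf(raw, df))
    return LRTResult(raw, df, p, bool(raw > chi2.ppf(0.95, df)))


# ---------------------------------------------------------------------------
# simulation (shared with synthetic_data)


def simulate_codon_alignment(
    tree: LabeledTree,
    spec: CodonModelSpec,
    params: dict,
    n_codons: int,
    seed: int,
    codon_freqs: np.ndarray | None = None,
) -> CodonAlignment:
    """Evolve codon sites along the tree under the given model.

    Root codons are drawn from the equilibrium frequencies; branch-site
    site classes are assigned per site from their proportions.  No stop
    codons can ever be emitted (the chain lives on the 61 sense codons).
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if spec.needs_foreground and not tree.has_foreground:
        raise ValueError(f"model {spec.model} requires a foreground (#1) branch mark")
    if codon_freqs is None:
        pi = np.full(N_SENSE, 1.0 / N_SENSE)
    else:
        pi = np.asarray(codon_freqs, dtype=float)
    rng = np.random.default_rng(seed)
    classes = _site_class_omegas(spec, params)
    props = np.array([c[0] for c in classes])
    site_class = rng.choice(len(classes), size=n_codons, p=props / props.sum())
    kappa = params["kappa"]
    cache: dict[float, _TransitionCache] = {}

    def P(omega: float, t: float) -> np.ndarray:
        if omega not in cache:
            cache[omega] = _TransitionCache(kappa, omega, pi)
        return cache[omega].P(t)

    root_state = rng.choice(N_SENSE, size=n_codons, p=pi / pi.sum())
    states: dict[int, np.ndarray] = {tree.nodes[-1].index: root_state}
    for n in reversed(tree.nodes[:-1]):  # preorder
        parent_state = states[n.parent]
        child = np.empty(n_codons, dtype=np.int64)
        for ci, (_, w_bg, w_fg) in enumerate(classes):
            mask = site_class == ci
            if not mask.any():
                continue
            w = w_fg if n.foreground else w_bg
            Pm = P(w, n.length)
            cum = Pm.cumsum(axis=1)
            u = rng.random(mask.sum())
            rows = cum[parent_state[mask]]
            child[mask] = (u[:, None] > rows).sum(axis=1)
        states[n.index] = child
    taxa, seqs = [], []
    for leaf in tree.leaves:
        taxa.append(leaf.taxon)
        seqs.append("".join(SENSE_CODONS[s] for s in states[leaf.index]))
    return CodonAlignment(taxa, seqs)
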