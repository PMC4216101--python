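"""GY94 codon-model likelihood engine and site-model positive-selection tests.

The model follows Goldman & Yang (1994): single-base codon exchanges with
transition/transversion ratio κ, nonsynonymous/synonymous ratio ω, and
equilibrium codon frequencies π (F3x4 by default).  Site-heterogeneous
models place a distribution over ω:

* M0   — one ω shared by all sites;
* M8   — a beta(p, q) discretized into K equal-probability classes with
         total weight p0, plus one class at ω_s ≥ 1 with weight 1 − p0;
* M8a  — M8 with ω_s fixed at 1 (the null of the positive-selection LRT).

The M8-vs-M8a likelihood-ratio statistic is referred to the 50:50 mixture of
χ²₀ and χ²₁ (the boundary null); naive empirical Bayes posteriors at the
MLEs identify sites in the ω_s class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .phylo import TreeNode, distance_matrix, nj_build
from .seq_io import GAP_CODON, CodingAlignment, GeneticCode, STANDARD_CODE

logger = logging.getLogger(__name__)

__all__ = [
    "CodonModelParams",
    "SiteModelFit",
    "sense_codons",
    "f3x4_frequencies",
    "gy94_rate_matrix",
    "transition_probabilities",
    "alignment_loglik",
    "fit_m0",
    "fit_m8",
    "fit_m8a",
    "lrt_m8_m8a",
    "neb_sites",
]


def sense_codons(code: GeneticCode = STANDARD_CODE) -> tuple[str, ...]:
    return code.sense_codons


_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


def _is_transition(x: str, y: str) -> bool:
    return frozenset((x, y)) in _TRANSITION_PAIRS


@dataclass
class CodonModelParams:
    """Parameters of a GY94 site-model: κ, an ω distribution, and π."""

    kappa: float
    omega_classes: np.ndarray  # ω value per class
    class_weights: np.ndarray  # probability per class, sums to 1
    pi: np.ndarray  # equilibrium frequencies over sense codons
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)
    extra: dict = field(default_factory=dict)  # p0, p, q, omega_s for M8-family

    def __post_init__(self) -> None:
        self.omega_classes = np.atleast_1d(np.asarray(self.omega_classes, float))
        self.class_weights = np.atleast_1d(np.asarray(self.class_weights, float))
        self.pi = np.asarray(self.pi, float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if (self.omega_classes < 0).any():
            raise ValueError("omega values must be nonnegative")
        if not np.isclose(self.class_weights.sum(), 1.0):
            raise ValueError("class weights must sum to 1")
        if len(self.pi) != len(self.code.sense_codons):
            raise ValueError("pi must cover the sense codons")
        if not np.isclose(self.pi.sum(), 1.0) or (self.pi <= 0).any():
            raise ValueError("pi must be a positive distribution")


def uniform_frequencies(code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    n = len(code.sense_codons)
    return np.full(n, 1.0 / n)


def f3x4_frequencies(
    aln: CodingAlignment, code: GeneticCode | None = None
) -> np.ndarray:
    """F3x4 codon frequencies: per-codon-position nucleotide frequencies,
    multiplied and renormalized over sense codons."""
    code = code or aln.code
    counts = np.full((3, 4), 1.0)  # +1 pseudocount keeps frequencies positive
    for seq in aln.sequences.values():
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "-" in codon:
                continue
            for k in range(3):
                counts[k, _NT_INDEX[codon[k]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, _NT_INDEX[c[0]]]
            * freqs[1, _NT_INDEX[c[1]]]
            * freqs[2, _NT_INDEX[c[2]]]
            for c in code.sense_codons
        ]
    )
    return pi / pi.sum()


def f61_frequencies(aln: CodingAlignment, code: GeneticCode | None = None) -> np.ndarray:
    """Observed sense-codon frequencies with a +1 pseudocount."""
    code = code or aln.code
    codons = code.sense_codons
    index = {c: i for i, c in enumerate(codons)}
    counts = np.ones(len(codons))
    for seq in aln.sequences.values():
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in index:
                counts[index[codon]] += 1
    return counts / counts.sum()


def _exchange_structure(code: GeneticCode):
    """Sparse structure of single-base codon exchanges: indices plus
    transition/synonymy masks (cached per genetic code)."""
    key = tuple(sorted(code.table.items()))
    cached = _exchange_structure._cache.get(key)
    if cached is not None:
        return cached
    codons = code.sense_codons
    n = len(codons)
    rows, cols, is_ts, is_syn = [], [], [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diffs = [k for k in range(3) if codons[i][k] != codons[j][k]]
            if len(diffs) != 1:
                continue
            (k,) = diffs
            rows.append(i)
            cols.append(j)
            is_ts.append(_is_transition(codons[i][k], codons[j][k]))
            is_syn.append(code.table[codons[i]] == code.table[codons[j]])
    cached = (
        np.array(rows),
        np.array(cols),
        np.array(is_ts, bool),
        np.array(is_syn, bool),
    )
    _exchange_structure._cache[key] = cached
    return cached


_exchange_structure._cache = {}


def _unscaled_q(kappa: float, omega: float, pi: np.ndarray, code: GeneticCode):
    rows, cols, is_ts, is_syn = _exchange_structure(code)
    n = len(pi)
    Q = np.zeros((n, n))
    rate = pi[cols].copy()
    rate[is_ts] *= kappa
    rate[~is_syn] *= omega
    Q[rows, cols] = rate
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    return Q


def gy94_rate_matrix(
    kappa: float,
    omega: float,
    pi: np.ndarray,
    code: GeneticCode = STANDARD_CODE,
    normalize: bool = True,
) -> np.ndarray:
    """GY94 generator over sense codons.

    Off-diagonal rates are π_j, multiplied by κ for transitions and ω for
    nonsynonymous changes; multi-step exchanges have rate 0.  With
    ``normalize`` the matrix is scaled so the mean rate at stationarity
    (−Σ π_i q_ii) is 1 substitution per unit time.
    """
    Q = _unscaled_q(kappa, omega, np.asarray(pi, float), code)
    if normalize:
        mean_rate = -float(np.dot(pi, np.diag(Q)))
        if mean_rate > 0:
            Q = Q / mean_rate
    return Q


def _mixture_rate_matrices(params: CodonModelParams) -> list[np.ndarray]:
    """Per-class generators sharing one mixture-averaged scale factor.

    Classes keep their relative speeds (higher-ω classes evolve faster);
    the expected rate averaged over classes and stationarity is 1, so branch
    lengths are in expected substitutions per codon under the mixture.
    """
    qs = [
        _unscaled_q(params.kappa, float(w), params.pi, params.code)
        for w in params.omega_classes
    ]
    mean_rate = sum(
        -float(np.dot(params.pi, np.diag(q))) * float(wt)
        for q, wt in zip(qs, params.class_weights)
    )
    if mean_rate <= 0:
        mean_rate = 1.0
    return [q / mean_rate for q in qs]


def transition_probabilities(Q: np.ndarray, t: float, pi: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for a reversible generator, via the π-symmetrized
    eigendecomposition.  Rows sum to 1; tiny negative entries are clipped."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    decomp = _eigendecompose(Q, pi)
    return _probs_from_decomposition(decomp, t)


def _eigendecompose(Q: np.ndarray, pi: np.ndarray):
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)  # enforce exact symmetry before eigh
    eigval, eigvec = np.linalg.eigh(S)
    left = eigvec / sqrt_pi[:, None]
    right = eigvec * sqrt_pi[:, None]
    return eigval, left, right


def _probs_from_decomposition(decomp, t: float) -> np.ndarray:
    eigval, left, right = decomp
    P = (left * np.exp(eigval * t)) @ right.T
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass
class SiteModelFit:
    """A fitted codon site-model: parameters, likelihood and NEB posteriors."""

    model: str
    params: CodonModelParams
    lnL: float
    tree: TreeNode
    site_class_loglik: np.ndarray | None = None  # (n_classes, n_sites)
    site_positions: list[int] | None = None  # reference AA coordinate per site

    @property
    def site_posteriors(self) -> np.ndarray:
        """Per-site posterior over ω classes (NEB at the MLEs)."""
        if self.site_class_loglik is None:
            raise ValueError("fit carries no per-site likelihoods")
        logw = np.log(self.params.class_weights)[:, None]
        joint = logw + self.site_class_loglik
        joint -= joint.max(axis=0, keepdims=True)
        post = np.exp(joint)
        return post / post.sum(axis=0, keepdims=True)


def _encode_alignment(aln: CodingAlignment, code: GeneticCode):
    """Codon-index matrix (taxa x sites); -1 encodes gap/ambiguous = missing."""
    codons = code.sense_codons
    index = {c: i for i, c in enumerate(codons)}
    n_sites = aln.n_codons
    mat = np.full((len(aln.taxa), n_sites), -1, dtype=int)
    for ti, taxon in enumerate(aln.taxa):
        seq = aln.sequences[taxon]
        for si in range(n_sites):
            codon = seq[3 * si : 3 * si + 3]
            if codon in index:
                mat[ti, si] = index[codon]
            elif codon != GAP_CODON and "-" not in codon:
                logger.debug("treating codon %r as missing data", codon)
    return mat


class _PruningEngine:
    """Felsenstein pruning over site patterns for a fixed tree and data."""

    def __init__(self, aln: CodingAlignment, tree: TreeNode, code: GeneticCode):
        self.code = code
        self.n_states = len(code.sense_codons)
        order = list(tree.postorder())
        self.nodes = order
        self.node_index = {id(n): i for i, n in enumerate(order)}
        self.tree = tree
        taxa_index = {t: i for i, t in enumerate(aln.taxa)}
        data = _encode_alignment(aln, code)
        leaf_rows = []
        for node in order:
            if node.is_leaf():
                if node.name not in taxa_index:
                    raise ValueError(f"tree leaf {node.name!r} not in alignment")
                leaf_rows.append(data[taxa_index[node.name]])
        tree_leaves = [n.name for n in order if n.is_leaf()]
        if set(tree_leaves) != set(aln.taxa):
            raise ValueError("tree leaves and alignment taxa differ")
        full = np.stack(leaf_rows)  # (n_leaves, n_sites) in postorder leaf order
        self.patterns, inverse, counts = np.unique(
            full.T, axis=0, return_inverse=True, return_counts=True
        )
        self.pattern_counts = counts.astype(float)
        self.pattern_of_site = inverse
        self.n_sites = full.shape[1]

    def class_site_loglik(self, Q: np.ndarray, pi: np.ndarray, scale: float = 1.0):
        """Per-site log-likelihood for one rate matrix (one ω class)."""
        decomp = _eigendecompose(Q, pi)
        n_pat = self.patterns.shape[0]
        partials: dict[int, np.ndarray] = {}
        log_scaler = np.zeros(n_pat)
        leaf_counter = 0
        for node in self.nodes:
            if node.is_leaf():
                states = self.patterns[:, leaf_counter]
                leaf_counter += 1
                part = np.zeros((n_pat, self.n_states))
                missing = states < 0
                part[missing, :] = 1.0
                observed = ~missing
                part[np.nonzero(observed)[0], states[observed]] = 1.0
            else:
                part = np.ones((n_pat, self.n_states))
                for child in node.children:
                    P = _probs_from_decomposition(
                        decomp, max(child.length, 0.0) * scale
                    )
                    part = part * (partials.pop(id(child)) @ P.T)
                # rescale to avoid underflow on deep trees
                norm = part.max(axis=1, keepdims=True)
                norm[norm == 0] = 1.0
                part = part / norm
                log_scaler += np.log(norm[:, 0])
            partials[id(node)] = part
        root_part = partials[id(self.tree)]
        site_lik = root_part @ pi
        with np.errstate(divide="ignore"):
            pat_loglik = np.log(site_lik) + log_scaler
        if not np.isfinite(pat_loglik).all():
            bad = int(np.nonzero(~np.isfinite(pat_loglik))[0][0])
            site = int(np.nonzero(self.pattern_of_site == bad)[0][0]) + 1
            raise ValueError(f"zero site likelihood at codon site {site}")
        return pat_loglik[self.pattern_of_site]

    def mixture_loglik(self, params: CodonModelParams, scale: float = 1.0):
        """(total lnL, per-class per-site log-likelihood matrix)."""
        qs = _mixture_rate_matrices(params)
        class_loglik = np.stack(
            [self.class_site_loglik(q, params.pi, scale) for q in qs]
        )
        logw = np.log(params.class_weights)[:, None]
        joint = logw + class_loglik
        m = joint.max(axis=0)
        site_loglik = m + np.log(np.exp(joint - m).sum(axis=0))
        return float(site_loglik.sum()), class_loglik


def alignment_loglik(
    aln: CodingAlignment,
    tree: TreeNode,
    params: CodonModelParams,
) -> float:
    """Log-likelihood of a codon alignment under a GY94 site-model.

    Felsenstein pruning per site; the site likelihood mixes the ω classes by
    their weights; gap codons are missing data (all-ones partials).
    """
    engine = _PruningEngine(aln, tree, params.code)
    lnL, _ = engine.mixture_loglik(params)
    return lnL


def _beta_class_medians(p: float, q: float, k: int) -> np.ndarray:
    """Medians of k equal-probability classes of a beta(p, q)."""
    quantiles = (np.arange(k) + 0.5) / k
    return stats.beta.ppf(quantiles, p, q)


def _m8_params(
    kappa: float,
    p0: float,
    p: float,
    q: float,
    omega_s: float,
    pi: np.ndarray,
    code: GeneticCode,
    k_classes: int,
) -> CodonModelParams:
    omegas = np.append(_beta_class_medians(p, q, k_classes), omega_s)
    weights = np.append(np.full(k_classes, p0 / k_classes), 1.0 - p0)
    weights = np.clip(weights, 1e-12, None)
    weights = weights / weights.sum()
    return CodonModelParams(
        kappa=kappa,
        omega_classes=omegas,
        class_weights=weights,
        pi=pi,
        code=code,
        extra={"p0": p0, "p": p, "q": q, "omega_s": omega_s},
    )


def _initial_tree(aln: CodingAlignment) -> TreeNode:
    """NJ tree on T3P distances, branch lengths converted to per-codon scale."""
    tree = nj_build(distance_matrix(aln))
    for node in tree.postorder():
        node.length = max(node.length, 1e-4) * 3.0  # nt sites -> codon units
    return tree


def _optimize(fun, x0_list, maxiter):
    best = None
    for x0 in x0_list:
        res = optimize.minimize(
            fun, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("optimizer failed on all restarts")
    return best


def _optimize_branch_lengths(engine, tree, make_params, maxiter):
    """Global branch-scale optimization followed by per-branch passes."""
    params = make_params()

    def neg_scale(logs):
        try:
            lnL, _ = engine.mixture_loglik(params, scale=float(np.exp(logs[0])))
            return -lnL
        except (ValueError, FloatingPointError):
            return 1e10

    res = optimize.minimize_scalar(
        lambda u: neg_scale([u]), bounds=(-6, 4), method="bounded",
        options={"xatol": 1e-3},
    )
    scale = float(np.exp(res.x))
    for node in tree.postorder():
        node.length *= scale
    # one coordinate pass over individual branches
    branches = [n for n in tree.postorder() if n is not tree]
    for node in branches:
        orig = node.length

        def neg_branch(logb):
            node.length = float(np.exp(logb))
            try:
                lnL, _ = engine.mixture_loglik(params)
                return -lnL
            except (ValueError, FloatingPointError):
                return 1e10

        r = optimize.minimize_scalar(
            neg_branch, bounds=(np.log(1e-6), np.log(20.0)), method="bounded",
            options={"xatol": 1e-3, "maxiter": 40},
        )
        if np.isfinite(r.fun):
            node.length = float(np.exp(r.x))
        else:
            node.length = orig
    return tree


def fit_m0(
    aln: CodingAlignment,
    tree: TreeNode | None = None,
    freq: str = "f3x4",
    seed: int = 0,
    restarts: int = 3,
    maxiter: int = 300,
    optimize_branches: bool = True,
) -> SiteModelFit:
    """Fit the one-ω model M0: maximizes lnL over (κ, ω) and branch lengths.

    Branch lengths start from NJ distances, get a global-scale fit, then one
    per-branch coordinate pass.  Restarts perturb the (κ, ω) start point.
    """
    code = aln.code
    pi = _frequencies(aln, freq, code)
    tree = tree.copy() if tree is not None else _initial_tree(aln)
    engine = _PruningEngine(aln, tree, code)
    rng = np.random.default_rng(seed)

    def neg(x):
        kappa, omega = np.exp(x)
        if not (1e-3 < kappa < 1e3 and 1e-5 < omega < 1e2):
            return 1e10
        params = CodonModelParams(
            kappa=kappa, omega_classes=[omega], class_weights=[1.0], pi=pi, code=code
        )
        try:
            lnL, _ = engine.mixture_loglik(params)
            return -lnL
        except (ValueError, FloatingPointError):
            return 1e10

    starts = [np.log([2.0, 0.3])]
    for _ in range(max(restarts - 1, 0)):
        starts.append(np.log([2.0, 0.3]) + rng.normal(0, 0.7, size=2))
    best = _optimize(neg, starts, maxiter)
    kappa, omega = np.exp(best.x)

    if optimize_branches:
        make = lambda: CodonModelParams(
            kappa=kappa, omega_classes=[omega], class_weights=[1.0], pi=pi, code=code
        )
        tree = _optimize_branch_lengths(engine, tree, make, maxiter)
        best = _optimize(neg, [best.x], maxiter)
        kappa, omega = np.exp(best.x)

    params = CodonModelParams(
        kappa=kappa, omega_classes=[omega], class_weights=[1.0], pi=pi, code=code,
        extra={"omega": float(omega)},
    )
    lnL, class_ll = engine.mixture_loglik(params)
    return SiteModelFit(
        model="M0", params=params, lnL=lnL, tree=tree,
        site_class_loglik=class_ll,
        site_positions=_site_positions(aln),
    )


def _frequencies(aln: CodingAlignment, freq: str, code: GeneticCode) -> np.ndarray:
    if freq == "f3x4":
        return f3x4_frequencies(aln, code)
    if freq == "f61":
        return f61_frequencies(aln, code)
    if freq == "uniform":
        return uniform_frequencies(code)
    raise ValueError(f"unknown frequency model {freq!r}")


def _site_positions(aln: CodingAlignment) -> list[int]:
    """Reference AA coordinate for each alignment codon column (insertions
    relative to the reference get the preceding reference position)."""
    ref = aln.sequences[aln.reference]
    positions = []
    pos = 0
    for i in range(aln.n_codons):
        if ref[3 * i : 3 * i + 3] != GAP_CODON:
            pos += 1
        positions.append(max(pos, 1))
    return positions


def _fit_m8_family(
    aln: CodingAlignment,
    tree: TreeNode,
    fix_omega_s: bool,
    freq: str,
    k_classes: int,
    seed: int,
    restarts: int,
    maxiter: int,
    start: np.ndarray | None = None,
) -> SiteModelFit:
    code = aln.code
    pi = _frequencies(aln, freq, code)
    engine = _PruningEngine(aln, tree, code)
    rng = np.random.default_rng(seed)

    def unpack(x):
        kappa = float(np.exp(x[0]))
        p0 = float(1.0 / (1.0 + np.exp(-x[1])))  # logit
        p = float(np.exp(x[2]))
        q = float(np.exp(x[3]))
        omega_s = 1.0 if fix_omega_s else 1.0 + float(np.exp(x[4]))
        return kappa, p0, p, q, omega_s

    def neg(x):
        kappa, p0, p, q, omega_s = unpack(x)
        if not (1e-3 < kappa < 1e3 and 1e-3 < p < 50 and 1e-3 < q < 50
                and omega_s < 1e2):
            return 1e10
        try:
            params = _m8_params(kappa, p0, p, q, omega_s, pi, code, k_classes)
            lnL, _ = engine.mixture_loglik(params)
            return -lnL
        except (ValueError, FloatingPointError):
            return 1e10

    n_free = 4 if fix_omega_s else 5
    base = np.array([np.log(2.0), 2.0, np.log(0.5), np.log(1.5), np.log(1.0)])[:n_free]
    starts = []
    if start is not None:
        starts.append(np.asarray(start, float)[:n_free])
    starts.append(base)
    for _ in range(max(restarts - 1, 0)):
        starts.append(base + rng.normal(0, 0.5, size=n_free))
    best = _optimize(neg, starts, maxiter)
    kappa, p0, p, q, omega_s = unpack(best.x)
    params = _m8_params(kappa, p0, p, q, omega_s, pi, code, k_classes)
    lnL, class_ll = engine.mixture_loglik(params)
    fit = SiteModelFit(
        model="M8a" if fix_omega_s else "M8",
        params=params,
        lnL=lnL,
        tree=tree,
        site_class_loglik=class_ll,
        site_positions=_site_positions(aln),
    )
    fit.params.extra["_opt_x"] = [float(v) for v in best.x]
    return fit


def fit_m8a(
    aln: CodingAlignment,
    tree: TreeNode,
    freq: str = "f3x4",
    k_classes: int = 10,
    seed: int = 0,
    restarts: int = 3,
    maxiter: int = 400,
) -> SiteModelFit:
    """Fit M8a (beta + ω_s = 1), branch lengths held fixed (take them from
    a preceding M0 fit)."""
    return _fit_m8_family(
        aln, tree, True, freq, k_classes, seed, restarts, maxiter
    )


def fit_m8(
    aln: CodingAlignment,
    tree: TreeNode,
    freq: str = "f3x4",
    k_classes: int = 10,
    seed: int = 0,
    restarts: int = 3,
    maxiter: int = 400,
    m8a_fit: SiteModelFit | None = None,
) -> SiteModelFit:
    """Fit M8 (beta + free ω_s ≥ 1), branch lengths held fixed.

    If an M8a fit is supplied, its optimum seeds one M8 start (with ω_s just
    above 1) which guarantees lnL(M8) ≥ lnL(M8a) up to optimizer tolerance.
    """
    start = None
    if m8a_fit is not None:
        x = m8a_fit.params.extra.get("_opt_x")
        if x is not None:
            start = np.append(np.asarray(x, float), np.log(1e-4))
    return _fit_m8_family(
        aln, tree, False, freq, k_classes, seed, restarts, maxiter, start=start
    )


def lrt_m8_m8a(fit8: SiteModelFit, fit8a: SiteModelFit) -> tuple[float, float]:
    """Likelihood-ratio test of M8 against M8a.

    The statistic 2(lnL₈ − lnL₈ₐ) is referred to the 50:50 mixture of χ²₀
    and χ²₁ (boundary null): p = ½·P(χ²₁ ≥ stat) for stat > 0, and p = 1 at
    stat = 0.  Negative statistics are clamped to 0 with a warning.
    """
    if fit8.model != "M8" or fit8a.model != "M8a":
        raise ValueError(f"expected (M8, M8a) fits, got ({fit8.model}, {fit8a.model})")
    if fit8.site_class_loglik is not None and fit8a.site_class_loglik is not None:
        if fit8.site_class_loglik.shape[1] != fit8a.site_class_loglik.shape[1]:
            raise ValueError("fits are on different data")
    stat = 2.0 * (fit8.lnL - fit8a.lnL)
    if stat < 0:
        logger.warning("negative LRT statistic %.4f clamped to 0", stat)
        stat = 0.0
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return stat, p


def neb_sites(
    fit8: SiteModelFit, threshold: float = 0.95
) -> list[tuple[int, float]]:
    """Sites whose NEB posterior for the ω_s (> 1) class exceeds threshold.

    Returns (reference AA position, posterior) pairs.  Under M8a (ω_s = 1)
    no class has ω > 1 and the list is empty.
    """
    if fit8.model not in {"M8", "M8a"}:
        raise ValueError(f"NEB site identification needs an M8-family fit, "
                         f"got {fit8.model}")
    selected_classes = fit8.params.omega_classes > 1.0
    if not selected_classes.any():
        return []
    post = fit8.site_posteriors[selected_classes].sum(axis=0)
    positions = fit8.site_positions or list(range(1, len(post) + 1))
    return [
        (positions[i], float(post[i]))
        for i in range(len(post))
        if post[i] > threshold
    ]
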