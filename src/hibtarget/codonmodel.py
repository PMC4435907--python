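"""Codon-substitution branch models (GY94 family) with ML fitting and LRTs.

The rate matrix follows Goldman–Yang: single-nucleotide codon changes occur
at rate proportional to the target codon's equilibrium frequency, multiplied
by the transition/transversion ratio κ for transitions and by ω (= dN/dS)
for amino-acid-changing substitutions.  Branch models share ω across all
branches (one-ratio), fix it at 1, give every branch its own ω (free-ratio),
or split ω between labeled foreground branches and the background
(two-ratio).  Likelihoods are computed by Felsenstein pruning over the 61
sense codons with alignment columns compressed to unique site patterns.
"""

from __future__ import annotations

import itertools
from collections import OrderedDict
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, stats

NUCS = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
N_CODONS = len(SENSE_CODONS)  # 61 under the standard code
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_GENETIC_CODE = {}
_BASES_FOR_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
_GENETIC_CODE.update(_BASES_FOR_CODE)

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _pair_class() -> tuple[np.ndarray, np.ndarray]:
    """(is_single_change & multiplier class) for all sense-codon pairs.

    Returns boolean matrices: is_transition, is_nonsynonymous for pairs that
    differ at exactly one position (others flagged by is_single == False).
    """
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transit = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transit[i, j] = frozenset(diffs[0]) in _TRANSITIONS
            nonsyn[i, j] = _GENETIC_CODE[ci] != _GENETIC_CODE[cj]
    return single, transit, nonsyn


_SINGLE, _TRANSIT, _NONSYN = _pair_class()


def translate(cds: str) -> str:
    """Translate an in-frame CDS; '---' codons become '-', trailing stop dropped."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    cds = cds.upper()
    out = []
    n = len(cds) // 3
    for k in range(n):
        codon = cds[3 * k : 3 * k + 3]
        if codon == "---":
            out.append("-")
        elif codon in STOP_CODONS:
            if k == n - 1:
                break  # trailing stop
            raise ValueError(f"internal stop codon {codon} at codon {k + 1}")
        elif codon in _GENETIC_CODE:
            out.append(_GENETIC_CODE[codon])
        elif any(b not in NUCS for b in codon):
            out.append("X")
        else:  # pragma: no cover
            raise ValueError(f"unrecognized codon {codon}")
    return "".join(out)


@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa/sequence count mismatch")
        lens = {len(s) for s in self.sequences}
        if len(lens) != 1:
            raise ValueError("alignment rows differ in length")
        (L,) = lens
        if L % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]
        for name, seq in zip(self.taxa, self.sequences):
            for k in range(L // 3):
                codon = seq[3 * k : 3 * k + 3]
                if codon in STOP_CODONS and k < L // 3 - 1:
                    raise ValueError(f"internal stop codon in {name}")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon_matrix(self) -> np.ndarray:
        """(n_taxa, n_codons) sense-codon indices, -1 for gap/ambiguous/stop."""
        mat = np.full((len(self.taxa), self.n_codons), -1, dtype=np.int64)
        for r, seq in enumerate(self.sequences):
            for k in range(self.n_codons):
                mat[r, k] = CODON_INDEX.get(seq[3 * k : 3 * k + 3], -1)
        return mat

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from Bio import SeqIO

        taxa, seqs = [], []
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                taxa.append(rec.id)
                seqs.append(str(rec.seq))
        return cls(taxa, seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.taxa, self.sequences):
                fh.write(f">{name}\n{seq}\n")


def f3x4_frequencies(aln: CodonAlignment, floor: float = 1e-4) -> np.ndarray:
    """F3x4 codon frequencies: per-codon-position nucleotide compositions."""
    pos_counts = np.zeros((3, 4))
    nuc_index = {b: i for i, b in enumerate(NUCS)}
    for seq in aln.sequences:
        for k in range(len(seq) // 3):
            codon = seq[3 * k : 3 * k + 3]
            for p, b in enumerate(codon):
                if b in nuc_index:
                    pos_counts[p, nuc_index[b]] += 1
    pos_freq = pos_counts + floor * pos_counts.sum(axis=1, keepdims=True).clip(min=1)
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nuc_index[c[0]]]
            * pos_freq[1, nuc_index[c[1]]]
            * pos_freq[2, nuc_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f61_frequencies(aln: CodonAlignment, floor: float = 0.5) -> np.ndarray:
    counts = np.full(N_CODONS, floor)
    for seq in aln.sequences:
        for k in range(len(seq) // 3):
            i = CODON_INDEX.get(seq[3 * k : 3 * k + 3])
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def gy94_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """GY94 generator over the 61 sense codons.

    Off-diagonal: 0 for multi-nucleotide changes; π_j, κπ_j, ωπ_j, ωκπ_j for
    synonymous transversion/transition and nonsynonymous transversion/
    transition.  Rows sum to zero; when ``scale`` the matrix is normalised so
    the expected substitution rate at equilibrium, −Σ_i π_i q_ii, equals 1
    (branch lengths in expected substitutions per codon).
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    mult = np.where(_TRANSIT, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    Q = np.where(_SINGLE, mult * pi[None, :], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        rate = -float(pi @ np.diag(Q))
        if rate > 0:
            Q = Q / rate
    return Q


def substitution_split(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """(nonsynonymous, synonymous) share of the unit substitution rate."""
    Q = gy94_rate_matrix(kappa, omega, pi, scale=True)
    flux = pi[:, None] * Q
    nonsyn_rate = float(flux[_NONSYN & _SINGLE].sum())
    syn_rate = float(flux[~_NONSYN & _SINGLE].sum())
    return nonsyn_rate, syn_rate


class _EigenQ:
    """Eigendecomposition of a reversible Q for fast transition matrices."""

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        Q = gy94_rate_matrix(kappa, omega, pi, scale=True)
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)  # symmetrize against round-off
        lam, U = np.linalg.eigh(S)
        self.lam = lam
        self.left = U / sqrt_pi[:, None]
        self.right = (U * sqrt_pi[:, None]).T

    def transition(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


@dataclass
class CodonModelParams:
    kappa: float
    omegas: dict[int, float]  # branch class -> omega
    pi: np.ndarray
    branch_lengths: dict[int, float] | None = None  # edge key -> length

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if any(w < 0 for w in self.omegas.values()):
            raise ValueError("omega must be >= 0")
        pi = np.asarray(self.pi, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        self.pi = pi


@dataclass
class BranchInfo:
    name: str
    length: float
    branch_class: int
    omega: float
    n_dn: float
    s_ds: float


@dataclass
class BranchModelFit:
    model: str
    np_: int
    lnl: float
    kappa: float
    omegas: dict[int, float]
    pi: np.ndarray
    branch_lengths: np.ndarray
    branches: list[BranchInfo]
    converged: bool
    n_restarts_used: int = 0
    message: str = ""


MODELS = ("one_ratio", "fixed_omega1", "free_ratio", "two_ratio")


class BranchLikelihood:
    """Felsenstein-pruning log-likelihood for one tree + codon alignment.

    Branch-length and ω parameters are mapped onto edges; repeated calls
    cache eigendecompositions by (κ, ω) and per-edge transition matrices by
    (κ, ω, t), which makes finite-difference gradients cheap.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        aln: CodonAlignment,
        branch_classes: dict[int, int] | None = None,
        pi: np.ndarray | None = None,
    ):
        self.aln = aln
        self.pi = f3x4_frequencies(aln) if pi is None else np.asarray(pi, float)
        taxa = set(aln.taxa)
        tip_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if tip_names != taxa:
            raise ValueError(
                f"tree tips and alignment taxa differ: {tip_names ^ taxa}"
            )
        # postorder node indexing; root last
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.root_index = self.n_nodes - 1
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in nodes]
        self.is_tip = np.zeros(self.n_nodes, dtype=bool)
        self.tip_row: dict[int, int] = {}
        self.edge_class = np.zeros(self.n_nodes, dtype=np.int64)
        self.edge_length0 = np.zeros(self.n_nodes)
        self.branch_names: list[str] = [""] * self.n_nodes
        row_of = {name: r for r, name in enumerate(aln.taxa)}
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                self.children[index[id(nd.parent_node)]].append(i)
                self.edge_length0[i] = (
                    nd.edge.length if nd.edge.length is not None else 0.1
                )
                if branch_classes:
                    self.edge_class[i] = branch_classes.get(id(nd), 0)
            if nd.is_leaf():
                self.is_tip[i] = True
                self.tip_row[i] = row_of[nd.taxon.label]
                self.branch_names[i] = nd.taxon.label
            else:
                kids = sorted(
                    index[id(c)] for c in nd.child_nodes()
                )
                self.branch_names[i] = "(" + ",".join(
                    self.branch_names[k].split("(")[0] or str(k) for k in kids
                )[:40] + ")"
        self.edge_nodes = [i for i in range(self.n_nodes) if i != self.root_index]
        self.n_branches = len(self.edge_nodes)
        # pattern compression
        mat = aln.codon_matrix()
        patterns, weights = np.unique(mat, axis=1, return_counts=True)
        self.patterns = patterns  # (n_taxa, n_patterns)
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]
        self._eigen_cache: OrderedDict = OrderedDict()
        self._p_cache: list[OrderedDict] = [OrderedDict() for _ in range(self.n_nodes)]

    # -- caches ------------------------------------------------------------
    def _eigen(self, kappa: float, omega: float) -> _EigenQ:
        key = (round(kappa, 12), round(omega, 12))
        e = self._eigen_cache.get(key)
        if e is None:
            e = _EigenQ(kappa, omega, self.pi)
            self._eigen_cache[key] = e
            if len(self._eigen_cache) > 64:
                self._eigen_cache.popitem(last=False)
        return e

    def _transition(self, edge: int, kappa: float, omega: float, t: float):
        key = (round(kappa, 12), round(omega, 12), round(t, 14))
        cache = self._p_cache[edge]
        P = cache.get(key)
        if P is None:
            P = self._eigen(kappa, omega).transition(t)
            cache[key] = P
            if len(cache) > 6:
                cache.popitem(last=False)
        return P

    # -- likelihood --------------------------------------------------------
    def edge_omega(self, edge: int, omegas: dict[int, float]) -> float:
        return omegas[self.edge_class[edge]]

    def log_likelihood(
        self, kappa: float, omegas: dict[int, float], branch_lengths: np.ndarray
    ) -> float:
        """lnL by pruning; ``branch_lengths`` indexed like ``edge_nodes``."""
        if self.n_nodes == 1:
            # single taxon, no branches: lnL = sum over columns of log pi
            obs = self.patterns[0]
            site = np.where(obs >= 0, self.pi[np.clip(obs, 0, None)], 1.0)
            return float(self.weights @ np.log(site))
        npat = self.n_patterns
        partial = {}
        logscale = np.zeros(npat)
        bl = {e: branch_lengths[k] for k, e in enumerate(self.edge_nodes)}
        for i in range(self.n_nodes):
            if self.is_tip[i]:
                continue
            acc = np.ones((npat, N_CODONS))
            for c in self.children[i]:
                omega = self.edge_omega(c, omegas)
                P = self._transition(c, kappa, omega, bl[c])
                if self.is_tip[c]:
                    obs = self.patterns[self.tip_row[c]]
                    PT_ext = np.vstack([P.T, np.ones(N_CODONS)])
                    acc *= PT_ext[obs]  # obs == -1 -> missing row of ones
                else:
                    acc *= partial.pop(c) @ P.T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            acc /= mx[:, None]
            logscale += np.log(mx)
            partial[i] = acc
        site = partial[self.root_index] @ self.pi
        return float(self.weights @ (np.log(site) + logscale))

    # -- fitting -----------------------------------------------------------
    def _model_classes(self, model: str) -> list[int]:
        """Distinct ω classes under the model (class ids used on edges)."""
        if model in ("one_ratio", "fixed_omega1"):
            return [0]
        if model == "two_ratio":
            labels = sorted(set(self.edge_class[e] for e in self.edge_nodes))
            if labels == [0]:
                raise ValueError("two_ratio requires at least one labeled branch")
            return labels
        if model == "free_ratio":
            return list(range(self.n_branches))
        raise ValueError(f"unknown model {model!r}")

    def count_np(self, model: str) -> int:
        if model == "fixed_omega1":
            return self.n_branches + 1
        return self.n_branches + 1 + len(self._model_classes(model))


def fit_branch_model(
    tree: dendropy.Tree,
    aln: CodonAlignment,
    model: str,
    branch_classes: dict[int, int] | None = None,
    pi: np.ndarray | None = None,
    seed: int = 0,
    n_restarts: int = 2,
    init: dict | None = None,
    maxiter: int = 400,
    ftol: float = 1e-9,
) -> BranchModelFit:
    """Maximise the branch-model likelihood over κ, branch lengths, and ω.

    ``init`` may give starting values (``kappa``, ``omega`` scalar or per
    class, ``branch_lengths``).  Free- and two-ratio fits warm-start from a
    one-ratio fit unless an explicit ``init`` is supplied.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    engine = BranchLikelihood(tree, aln, branch_classes=branch_classes, pi=pi)
    if model in ("free_ratio", "two_ratio") and init is None:
        base = _fit_engine(engine, "one_ratio", seed, n_restarts, None, maxiter, ftol)
        init = {
            "kappa": base.kappa,
            "omega": base.omegas[0],
            "branch_lengths": base.branch_lengths,
        }
    return _fit_engine(engine, model, seed, n_restarts, init, maxiter, ftol)


def _fit_engine(
    engine: BranchLikelihood,
    model: str,
    seed: int,
    n_restarts: int,
    init: dict | None,
    maxiter: int,
    ftol: float,
) -> BranchModelFit:
    rng = np.random.default_rng(seed)
    nb = engine.n_branches
    classes = engine._model_classes(model)
    free_omega = model != "fixed_omega1"
    n_omega = len(classes) if free_omega else 0

    if model == "free_ratio":
        # every edge its own class, in edge order
        class_of_edge = {e: k for k, e in enumerate(engine.edge_nodes)}
    elif model == "two_ratio":
        class_of_edge = {e: int(engine.edge_class[e]) for e in engine.edge_nodes}
    else:  # one shared omega (free or fixed at 1)
        class_of_edge = {e: 0 for e in engine.edge_nodes}

    def unpack(x):
        bl = np.exp(x[:nb])
        kappa = float(np.exp(x[nb]))
        if free_omega:
            om = np.exp(x[nb + 1 :])
            omegas = {cls: float(om[k]) for k, cls in enumerate(classes)}
        else:
            omegas = {0: 1.0}
        return kappa, omegas, bl

    def negloglik(x):
        kappa, omegas, bl = unpack(x)
        per_edge = {e: omegas[class_of_edge[e]] for e in engine.edge_nodes}
        # evaluate with per-edge omega lookup
        npat = engine.n_patterns
        partial = {}
        logscale = np.zeros(npat)
        bl_of = {e: bl[k] for k, e in enumerate(engine.edge_nodes)}
        for i in range(engine.n_nodes):
            if engine.is_tip[i]:
                continue
            acc = np.ones((npat, N_CODONS))
            for c in engine.children[i]:
                P = engine._transition(c, kappa, per_edge[c], bl_of[c])
                if engine.is_tip[c]:
                    obs = engine.patterns[engine.tip_row[c]]
                    PT_ext = np.vstack([P.T, np.ones(N_CODONS)])
                    acc *= PT_ext[obs]
                else:
                    acc *= partial.pop(c) @ P.T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            acc /= mx[:, None]
            logscale += np.log(mx)
            partial[i] = acc
        site = partial[engine.root_index] @ engine.pi
        return -float(engine.weights @ (np.log(site) + logscale))

    # starting point
    bl0 = np.clip(engine.edge_length0[engine.edge_nodes], 1e-4, 10.0)
    kappa0, omega0 = 2.0, 0.4
    if init:
        if "branch_lengths" in init and init["branch_lengths"] is not None:
            bl0 = np.clip(np.asarray(init["branch_lengths"], float), 1e-6, 50.0)
        kappa0 = float(init.get("kappa", kappa0))
        omega0 = init.get("omega", omega0)
    if np.isscalar(omega0):
        omega_vec0 = np.full(n_omega, float(omega0))
    else:
        omega_vec0 = np.asarray(omega0, float)

    bounds = (
        [(np.log(1e-6), np.log(50.0))] * nb
        + [(np.log(0.01), np.log(200.0))]
        + [(np.log(1e-4), np.log(99.0))] * n_omega
    )

    def pack(bl, kappa, omega_vec):
        parts = [np.log(np.clip(bl, 1e-6, 50.0)), [np.log(kappa)]]
        if n_omega:
            parts.append(np.log(np.clip(omega_vec, 1e-4, 99.0)))
        return np.concatenate([np.atleast_1d(p) for p in parts])

    starts = [pack(bl0, kappa0, omega_vec0)]
    for _ in range(max(0, n_restarts)):
        jitter_bl = bl0 * np.exp(rng.normal(0, 0.5, nb))
        jitter_kappa = kappa0 * np.exp(rng.normal(0, 0.3))
        jitter_omega = (
            omega_vec0 * np.exp(rng.normal(0, 0.5, n_omega)) if n_omega else omega_vec0
        )
        starts.append(pack(jitter_bl, jitter_kappa, jitter_omega))

    # the jittered starts are a fallback against failed or poor convergence
    best = None
    used = 0
    for x0 in starts:
        res = optimize.minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": ftol, "maxcor": 20},
        )
        used += 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("branch-model optimisation failed on all restarts")

    kappa, omegas, bl = unpack(best.x)
    if model == "free_ratio":
        omegas_by_class = omegas
    elif model == "fixed_omega1":
        omegas_by_class = {0: 1.0}
    else:
        omegas_by_class = omegas

    n_codons = engine.aln.n_codons
    branches = []
    for k, e in enumerate(engine.edge_nodes):
        om = omegas_by_class[class_of_edge[e]]
        rho_n, rho_s = substitution_split(kappa, om, engine.pi)
        branches.append(
            BranchInfo(
                name=engine.branch_names[e],
                length=float(bl[k]),
                branch_class=int(class_of_edge[e]),
                omega=float(om),
                n_dn=float(bl[k] * rho_n * n_codons),
                s_ds=float(bl[k] * rho_s * n_codons),
            )
        )
    return BranchModelFit(
        model=model,
        np_=engine.count_np(model),
        lnl=-float(best.fun),
        kappa=float(kappa),
        omegas={int(k): float(v) for k, v in omegas_by_class.items()},
        pi=engine.pi,
        branch_lengths=bl,
        branches=branches,
        converged=bool(best.success),
        n_restarts_used=used,
        message=str(best.message),
    )


@dataclass(frozen=True)
class LRTResult:
    stat: float
    df: int
    pvalue: float


def lrt(null_fit, alt_fit, tol: float = 1e-3) -> LRTResult:
    """Likelihood-ratio test of nested branch models.

    Accepts ``BranchModelFit`` objects or plain ``(lnl, np)`` pairs.  The
    statistic 2Δℓ is clamped at 0 within ``tol``; a more negative value
    signals an optimiser failure and raises.
    """
    lnl0, np0 = _lnl_np(null_fit)
    lnl1, np1 = _lnl_np(alt_fit)
    df = np1 - np0
    if df < 1:
        raise ValueError("alternative model must have more parameters than the null")
    stat = 2.0 * (lnl1 - lnl0)
    if stat < -tol:
        raise ValueError(
            f"negative LRT statistic {stat:.6f}: alternative fit is worse than the null"
        )
    stat = max(stat, 0.0)
    return LRTResult(stat=stat, df=df, pvalue=float(stats.chi2.sf(stat, df)))


def _lnl_np(fit) -> tuple[float, int]:
    if hasattr(fit, "lnl"):
        return float(fit.lnl), int(fit.np_)
    lnl, np_ = fit
    return float(lnl), int(np_)


def log_likelihood(
    tree: dendropy.Tree,
    aln: CodonAlignment,
    params: CodonModelParams,
    branch_classes: dict[int, int] | None = None,
) -> float:
    """One-shot pruning likelihood at fixed parameters.

    Branch lengths default to the tree's own edge lengths unless given in
    ``params.branch_lengths`` (keyed like ``BranchLikelihood.edge_nodes``).
    """
    engine = BranchLikelihood(tree, aln, branch_classes=branch_classes, pi=params.pi)
    bl = engine.edge_length0[engine.edge_nodes]
    omegas = dict(params.omegas)
    for e in engine.edge_nodes:
        omegas.setdefault(int(engine.edge_class[e]), params.omegas.get(0, 1.0))
    return engine.log_likelihood(params.kappa, omegas, bl)
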