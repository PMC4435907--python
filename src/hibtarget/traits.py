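"""Correlating a binary hibernation trait with genome-derived statistics.

Three routes, in increasing awareness of shared ancestry:

* a classic pooled-variance two-sample t-test,
* a simulation-based phylogenetic ANOVA (null F distribution obtained by
  simulating the trait under Brownian motion on the phylogeny),
* a quantitative-genetic threshold model: the binary state is the sign of a
  latent liability evolving by Brownian motion jointly with the continuous
  trait; their correlation r is sampled by MCMC.

Plus the 2^-ΔΔCt fold-change helper used for qPCR-style relative expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .phylo import phylo_covariance


@dataclass
class TraitTable:
    species: list[str]
    hibernator: np.ndarray  # 0/1 per species
    value: np.ndarray

    def __post_init__(self):
        self.hibernator = np.asarray(self.hibernator, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in trait table")
        if not set(np.unique(self.hibernator)) <= {0, 1}:
            raise ValueError("hibernator must be 0/1")

    @classmethod
    def from_tsv(cls, path) -> "TraitTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            species=list(df["species"]),
            hibernator=df["hibernator"].to_numpy(),
            value=df["value"].to_numpy(),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"species": self.species, "hibernator": self.hibernator, "value": self.value}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    pvalue: float


def students_t_test(
    values_h, values_n, welch: bool = False
) -> TTestResult:
    """Two-tailed two-sample t-test (pooled variance by default)."""
    x = np.asarray(values_h, float)
    y = np.asarray(values_n, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch:
        if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
            if x.mean() == y.mean():
                return TTestResult(t=0.0, df=len(x) + len(y) - 2, pvalue=1.0)
            raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = len(x) + len(y) - 2 if not welch else float(res.df)
    return TTestResult(t=float(res.statistic), df=df, pvalue=float(res.pvalue))


def brownian_simulate(
    tree: dendropy.Tree, rate: float, seed: int, n_rep: int
) -> tuple[list[str], np.ndarray]:
    """Simulate Brownian tip values; returns (taxa, matrix of shape (n_rep, n_tips))."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    taxa, C = phylo_covariance(tree)
    if np.any(np.diag(C) <= 0):
        raise ValueError("tree must have positive root-to-tip path lengths")
    L = np.linalg.cholesky(C * rate + 1e-12 * np.eye(len(taxa)))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_rep, len(taxa)))
    return taxa, Z @ L.T


def _anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA F for a binary grouping; vectorised over rows of values."""
    v = np.atleast_2d(values)
    g = groups.astype(bool)
    n1, n0 = g.sum(), (~g).sum()
    n = n1 + n0
    m1 = v[:, g].mean(axis=1)
    m0 = v[:, ~g].mean(axis=1)
    grand = v.mean(axis=1)
    ss_between = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    ss_within = ((v[:, g] - m1[:, None]) ** 2).sum(axis=1) + (
        (v[:, ~g] - m0[:, None]) ** 2
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / 1.0) / (ss_within / (n - 2))
    return F if values.ndim > 1 else float(F[0])


def pic_rate(tree: dendropy.Tree, traits: TraitTable) -> float:
    """Brownian rate from the GLS residual variance (equivalently, the mean
    squared phylogenetically independent contrast)."""
    taxa, C = phylo_covariance(tree)
    order = {s: i for i, s in enumerate(traits.species)}
    x = traits.value[[order[t] for t in taxa]]
    Cinv = np.linalg.inv(C + 1e-12 * np.eye(len(taxa)))
    one = np.ones(len(taxa))
    mu = (one @ Cinv @ x) / (one @ Cinv @ one)
    resid = x - mu
    return float(resid @ Cinv @ resid / (len(taxa) - 1))


@dataclass
class PhylANOVAResult:
    f_obs: float
    p_phyl: float
    n_sim: int
    seed: int
    f_sim_mean: float
    f_sim_q95: float


def phyl_anova(
    tree: dendropy.Tree, traits: TraitTable, n_sim: int = 1000, seed: int = 0
) -> PhylANOVAResult:
    """Phylogenetic ANOVA: observed F against Brownian-simulated null Fs.

    p = (1 + #{F_sim >= F_obs}) / (n_sim + 1).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    groups = np.unique(traits.hibernator)
    if len(groups) != 2:
        raise ValueError("both trait classes must be present")
    if np.allclose(traits.value, traits.value[0]):
        raise ValueError("constant trait values: F undefined")
    taxa, _ = phylo_covariance(tree)
    if set(taxa) != set(traits.species):
        raise ValueError("tree tips and trait species differ")
    order = {s: i for i, s in enumerate(traits.species)}
    idx = [order[t] for t in taxa]
    x = traits.value[idx]
    g = traits.hibernator[idx]
    f_obs = float(_anova_f(x[None, :], g)[0])
    rate = pic_rate(tree, traits)
    _, sims = brownian_simulate(tree, rate, seed=seed, n_rep=n_sim)
    f_sim = _anova_f(sims, g)
    p = (1.0 + float((f_sim >= f_obs).sum())) / (n_sim + 1.0)
    return PhylANOVAResult(
        f_obs=f_obs,
        p_phyl=p,
        n_sim=n_sim,
        seed=seed,
        f_sim_mean=float(f_sim.mean()),
        f_sim_q95=float(np.quantile(f_sim, 0.95)),
    )


@dataclass
class ThresholdPosterior:
    samples: np.ndarray  # post-burn-in r samples
    mean: float
    ci95: tuple[float, float]
    p_r_le_0: float
    n_gen: int
    burnin: int
    seed: int
    acceptance: dict[str, float]
    warning: str | None = None


def threshold_model_mcmc(
    tree: dendropy.Tree,
    traits: TraitTable,
    n_gen: int = 100_000,
    burnin_frac: float = 0.2,
    seed: int = 0,
    sample_every: int = 10,
) -> ThresholdPosterior:
    """Threshold-model correlation between a binary trait and a continuous one.

    The latent liability ℓ and the observed value x evolve as a joint
    Brownian process on the tree with trait covariance
    ``[[1, r·σ], [r·σ, σ²]]`` (liability scale fixed at 1 for
    identifiability); the observed binary state is 1 iff ℓ > 0 at the tip.
    One generation = a Metropolis sweep over all tip liabilities followed by
    updates of r (uniform prior on [−1, 1]), log σ, and the two root means.
    Returns post-burn-in samples of r, their mean, and the central 95%
    credible interval.
    """
    if n_gen < 100:
        raise ValueError("n_gen too small for any meaningful posterior")
    binary = np.asarray(traits.hibernator)
    if len(np.unique(binary)) < 2:
        raise ValueError("binary trait is constant: liability not identifiable")
    taxa, C = phylo_covariance(tree)
    if set(taxa) != set(traits.species):
        raise ValueError("tree tips and trait species differ")
    order = {s: i for i, s in enumerate(traits.species)}
    idx = [order[t] for t in taxa]
    x = traits.value[idx]
    b = binary[idx].astype(bool)
    n = len(taxa)
    rng = np.random.default_rng(seed)

    Cinv = np.linalg.inv(C + 1e-10 * np.eye(n))
    sign_logdet_C = np.linalg.slogdet(C + 1e-10 * np.eye(n))[1]

    # state
    liab = np.where(b, 0.5, -0.5) + 0.1 * rng.standard_normal(n)
    liab[b & (liab <= 0)] = 0.5
    liab[~b & (liab >= 0)] = -0.5
    sigma = max(float(x.std()), 1e-6)
    r = 0.0
    mu_l, mu_x = 0.0, float(x.mean())

    def trait_R(r_, sigma_):
        return np.array([[1.0, r_ * sigma_], [r_ * sigma_, sigma_**2]])

    def loglik(M, r_, sigma_):
        # M = Y' Cinv Y with Y = [liab - mu_l, x - mu_x]
        det_R = sigma_**2 * (1.0 - r_**2)
        if det_R <= 1e-12:
            return -np.inf
        Rinv = (
            np.array([[sigma_**2, -r_ * sigma_], [-r_ * sigma_, 1.0]]) / det_R
        )
        return -0.5 * (
            2 * n * math.log(2 * math.pi)
            + 2 * sign_logdet_C
            + n * math.log(det_R)
            + float(np.sum(Rinv * M))
        )

    Y = np.column_stack([liab - mu_l, x - mu_x])
    A = Cinv @ Y  # maintained incrementally
    M = Y.T @ A

    # proposal scales, adapted during burn-in
    step_l = np.full(n, 0.5)
    step_r, step_s, step_m = 0.2, 0.3, 0.3
    acc = {"liability": 0, "r": 0, "sigma": 0, "mu": 0}
    tries = {"liability": 0, "r": 0, "sigma": 0, "mu": 0}

    burnin = int(round(burnin_frac * n_gen))
    samples = []
    ll = loglik(M, r, sigma)
    diagC = np.diag(Cinv).copy()
    cinv_rowsum = Cinv.sum(axis=1)

    for gen in range(n_gen):
        # --- liability sweep (tip-wise Metropolis with sign constraint)
        for i in range(n):
            delta = step_l[i] * rng.standard_normal()
            new_li = liab[i] + delta
            tries["liability"] += 1
            if (new_li > 0) != b[i]:
                continue  # sign constraint: prior mass zero
            dM00 = 2 * delta * A[i, 0] + delta * delta * diagC[i]
            dM01 = delta * A[i, 1]
            M_new = M + np.array([[dM00, dM01], [dM01, 0.0]])
            ll_new = loglik(M_new, r, sigma)
            if math.log(rng.random()) < ll_new - ll:
                liab[i] = new_li
                A[:, 0] += delta * Cinv[:, i]
                M = M_new
                ll = ll_new
                acc["liability"] += 1
        # --- r update (uniform prior, reflect at the boundary)
        r_new = r + step_r * rng.standard_normal()
        while abs(r_new) > 1:
            r_new = math.copysign(2.0, r_new) - r_new
        tries["r"] += 1
        ll_new = loglik(M, r_new, sigma)
        if math.log(rng.random()) < ll_new - ll:
            r, ll = r_new, ll_new
            acc["r"] += 1
        # --- sigma update (log random walk; flat prior on log sigma)
        s_new = sigma * math.exp(step_s * rng.standard_normal())
        tries["sigma"] += 1
        ll_new = loglik(M, r, s_new)
        if math.log(rng.random()) < ll_new - ll:
            sigma, ll = s_new, ll_new
            acc["sigma"] += 1
        # --- root means (joint random-walk)
        dml = step_m * rng.standard_normal()
        dmx = step_m * sigma * rng.standard_normal()
        Y_new = np.column_stack([liab - (mu_l + dml), x - (mu_x + dmx)])
        A_new = A - np.column_stack([dml * cinv_rowsum, dmx * cinv_rowsum])
        M_new = Y_new.T @ A_new
        tries["mu"] += 1
        ll_new = loglik(M_new, r, sigma)
        if math.log(rng.random()) < ll_new - ll:
            mu_l, mu_x = mu_l + dml, mu_x + dmx
            A, M, ll = A_new, M_new, ll_new
            acc["mu"] += 1
        # --- adaptation during burn-in
        if gen < burnin and (gen + 1) % 200 == 0:
            frac = acc["liability"] / max(tries["liability"], 1)
            step_l *= math.exp(frac - 0.4)
            for key, attr in (("r", "step_r"), ("sigma", "step_s"), ("mu", "step_m")):
                fr = acc[key] / max(tries[key], 1)
                if key == "r":
                    step_r *= math.exp(fr - 0.3)
                elif key == "sigma":
                    step_s *= math.exp(fr - 0.3)
                else:
                    step_m *= math.exp(fr - 0.3)
            for k in acc:
                acc[k] = 0
                tries[k] = 0
        if gen >= burnin and (gen - burnin) % sample_every == 0:
            samples.append(r)

    samples = np.asarray(samples)
    rates = {k: acc[k] / max(tries[k], 1) for k in acc}
    warning = None
    if not (0.1 <= rates["r"] <= 0.9):
        warning = f"r-update acceptance rate {rates['r']:.2f} outside [0.1, 0.9]"
    lo, hi = np.quantile(samples, [0.025, 0.975])
    return ThresholdPosterior(
        samples=samples,
        mean=float(samples.mean()),
        ci95=(float(lo), float(hi)),
        p_r_le_0=float((samples <= 0).mean()),
        n_gen=n_gen,
        burnin=burnin,
        seed=seed,
        acceptance=rates,
        warning=warning,
    )


@dataclass(frozen=True)
class FoldChange:
    dct_state: float
    dct_baseline: float
    ddct: float
    fold: float


def ddct_fold_change(
    ct_target_state: float,
    ct_ref_state: float,
    ct_target_base: float,
    ct_ref_base: float,
) -> FoldChange:
    """Relative expression by the 2^-ΔΔCt method."""
    for v in (ct_target_state, ct_ref_state, ct_target_base, ct_ref_base):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    dct_state = ct_target_state - ct_ref_state
    dct_base = ct_target_base - ct_ref_base
    ddct = dct_state - dct_base
    return FoldChange(
        dct_state=dct_state,
        dct_baseline=dct_base,
        ddct=ddct,
        fold=2.0 ** (-ddct),
    )
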