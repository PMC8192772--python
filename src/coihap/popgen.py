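"""Population-genetic diversity summaries, neutrality tests, mismatch
distributions, AMOVA / Phi_ST and principal coordinates analysis.

All statistics operate on a :class:`~coihap.seqio.MultipleAlignment` of
haploid sequences.  Sites carrying ``N`` or ``-`` in either member of a
pair are excluded from that pair's comparison (pairwise deletion).

Notation
--------
h          Nei's unbiased haplotype diversity, N/(N-1) * (1 - sum p_i^2).
pi         nucleotide diversity: mean per-site pairwise difference.  Both
           the uncorrected value and the Jukes-Cantor corrected value
           (d = -3/4 ln(1 - 4p/3) applied per pair before averaging) are
           always reported, because published tables are ambiguous about
           which one they print.
S          number of segregating sites (>= 2 observed states).
K          mean number of pairwise nucleotide differences.
D          Tajima's D, the normalised difference between the pairwise
           (theta_pi = K) and Watterson (S/a1) estimators of theta.
Fs         Fu's Fs: with theta_hat = K, S' = P(k >= k_obs) under the Ewens
           sampling distribution of the number of alleles k in a sample
           of N, and Fs = ln(S' / (1 - S')).  Strongly negative when a
           sample carries more haplotypes than the stationary coalescent
           predicts, as after a demographic expansion.
Phi_ST     among-population fraction of molecular variance from a
           one-level AMOVA on pairwise difference counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc, gammaln, logsumexp

from .seqio import MultipleAlignment, PopulationMap, collapse_haplotypes

log = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


def encode_alignment(aln: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, valid): integer-coded sites and a mask of A/C/G/T."""
    n, L = aln.n, aln.length
    codes = np.empty((n, L), dtype=np.uint8)
    for i, seq in enumerate(aln.seqs):
        codes[i] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    # map ASCII to 0..5
    lut = np.zeros(256, dtype=np.uint8)
    for ch, v in _CODE.items():
        lut[ord(ch)] = v
    codes = lut[codes]
    valid = codes < 4
    return codes, valid


def pairwise_difference_matrix(
    aln: MultipleAlignment,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw pairwise difference counts and the number of compared sites.

    Returns two symmetric (n, n) arrays: ``diffs[i, j]`` is the number of
    mismatching sites among those where both sequences carry A/C/G/T, and
    ``compared[i, j]`` the number of such sites.
    """
    codes, valid = encode_alignment(aln)
    n = aln.n
    diffs = np.zeros((n, n), dtype=np.int64)
    compared = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        ne = (codes[i] != codes[i + 1 :]) & both
        d = ne.sum(axis=1)
        c = both.sum(axis=1)
        diffs[i, i + 1 :] = d
        diffs[i + 1 :, i] = d
        compared[i, i + 1 :] = c
        compared[i + 1 :, i] = c
    compared[np.diag_indices(n)] = valid.sum(axis=1)
    return diffs, compared


def _upper(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def segregating_sites(aln: MultipleAlignment) -> int:
    """Number of alignment columns with >= 2 observed A/C/G/T states."""
    codes, valid = encode_alignment(aln)
    S = 0
    for j in range(aln.length):
        states = set(codes[valid[:, j], j].tolist())
        if len(states) >= 2:
            S += 1
    return S


def nei_haplotype_diversity(counts: np.ndarray | list[int]) -> float:
    """Nei's unbiased haplotype diversity from haplotype counts.

    Returns NaN for N < 2 (not determined).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        return float("nan")
    p2 = float(np.sum((counts / n) ** 2))
    return n / (n - 1) * (1.0 - p2)


@dataclass(frozen=True)
class DiversitySummary:
    """One row of a per-population diversity table."""

    population: str
    N: int
    N_h: int
    N_p: int
    h: float
    pi_raw: float
    pi_jc: float
    S: int
    K: float


def _pi_pair_stats(aln: MultipleAlignment) -> tuple[float, float, float]:
    """(pi_raw, pi_jc, K) over all unordered pairs; NaN for N < 2."""
    if aln.n < 2:
        return float("nan"), float("nan"), float("nan")
    diffs, compared = pairwise_difference_matrix(aln)
    d = _upper(diffs).astype(float)
    c = _upper(compared).astype(float)
    ok = c > 0
    p = np.zeros_like(d)
    p[ok] = d[ok] / c[ok]
    pi_raw = float(p.mean())
    # Jukes-Cantor per pair; saturating pairs (p >= 3/4) yield inf
    with np.errstate(divide="ignore", invalid="ignore"):
        jc = -0.75 * np.log1p(-4.0 * p / 3.0)
    pi_jc = float(np.mean(jc))
    K = float(d.mean())
    return pi_raw, pi_jc, K


def diversity_summary(
    aln: MultipleAlignment,
    pops: PopulationMap | None = None,
    total_label: str = "Total",
) -> list[DiversitySummary]:
    """Per-population diversity rows plus a pooled row.

    N_p counts haplotypes confined to a single population.  For the pooled
    row N_p is the total number of such private haplotypes.  Populations of
    size 1 report h/pi/K as NaN (not determined).
    """
    table = collapse_haplotypes(aln, pops)
    rows: list[DiversitySummary] = []

    def _one(label: str, ids: list[str]) -> DiversitySummary:
        sub = aln.subset(ids)
        subtab = collapse_haplotypes(sub)
        counts = [h.count_total for h in subtab]
        pi_raw, pi_jc, K = _pi_pair_stats(sub)
        S = segregating_sites(sub) if sub.n >= 2 else 0
        if pops is not None:
            member_pops = {
                h.sequence: set(h.counts_by_population) for h in table
            }
            if label == total_label:
                N_p = sum(
                    1 for s, ps in member_pops.items() if len(ps) == 1
                )
            else:
                N_p = sum(
                    1
                    for h in subtab
                    if member_pops[h.sequence] == {label}
                )
        else:
            N_p = 0
        return DiversitySummary(
            population=label,
            N=sub.n,
            N_h=subtab.n_haplotypes,
            N_p=N_p,
            h=nei_haplotype_diversity(counts),
            pi_raw=pi_raw,
            pi_jc=pi_jc,
            S=S,
            K=K,
        )

    if pops is not None:
        pops.require_complete(aln)
        for pop in pops.populations():
            ids = [sid for sid in aln.ids if pops[sid] == pop]
            if ids:
                rows.append(_one(pop, ids))
    rows.append(_one(total_label, list(aln.ids)))
    return rows


# --------------------------------------------------------------------------
# Tajima's D
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """The 1989 closed-form constants for sample size n (n >= 2)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(aln: MultipleAlignment) -> float:
    """Tajima's D; NaN when not determined (N < 4 or S = 0)."""
    if aln.n < 4:
        return float("nan")
    S = segregating_sites(aln)
    if S == 0:
        return float("nan")
    _, _, K = _pi_pair_stats(aln)
    c = tajima_constants(aln.n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (K - S / c.a1) / math.sqrt(var)


# --------------------------------------------------------------------------
# Fu's Fs via the Ewens sampling distribution
# --------------------------------------------------------------------------

def log_unsigned_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n, via |s(n+1,k)| = |s(n,k-1)| + n|s(n,k)|.

    Computed in log space so rows up to n of a few hundred are stable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    row = np.full(n + 1, -np.inf)
    row[:2] = [-np.inf, 0.0]  # |s(1,1)| = 1
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        hi = min(m + 1, n) + 1
        prev = np.concatenate(([-np.inf], row[: hi - 1]))
        new[:hi] = np.logaddexp(prev, math.log(m) + row[:hi])
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(k alleles) for k = 1..n under the Ewens sampling distribution.

    P(k) = |s(n,k)| theta^k / theta^(n), with theta^(n) the rising
    factorial theta(theta+1)...(theta+n-1).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    row = log_unsigned_stirling_row(n)[1:]
    k = np.arange(1, n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return row + k * math.log(theta) - log_rising


@dataclass(frozen=True)
class FuFsResult:
    Fs: float
    s_prime: float
    theta_hat: float
    k_obs: int
    n: int


def fus_fs_from_counts(n: int, k_obs: int, theta: float) -> FuFsResult:
    """Fu's Fs from sample size, observed allele count and theta estimate.

    Evaluated fully in log space: Fs = log S' - log(1 - S') where the two
    tail sums are taken directly over the Ewens log-pmf, so neither tail
    underflows before the log-odds are formed.
    """
    if not (1 <= k_obs <= n):
        raise ValueError("need 1 <= k_obs <= n")
    lp = ewens_log_pmf(n, theta)
    log_tail = float(logsumexp(lp[k_obs - 1 :]))  # P(K >= k_obs)
    if k_obs == 1:
        return FuFsResult(float("nan"), 1.0, theta, k_obs, n)
    log_head = float(logsumexp(lp[: k_obs - 1]))  # P(K < k_obs)
    Fs = log_tail - log_head
    if not np.isfinite(Fs):
        log.warning("Fu's Fs underflowed to %r (n=%d, k=%d)", Fs, n, k_obs)
    return FuFsResult(Fs, math.exp(log_tail), theta, k_obs, n)


def fus_fs(aln: MultipleAlignment) -> FuFsResult:
    """Fu's Fs with theta_hat = K (mean pairwise differences) and k_obs =
    the number of distinct haplotypes.  NaN when K = 0 or k_obs = 1."""
    table = collapse_haplotypes(aln)
    k_obs = table.n_haplotypes
    _, _, K = _pi_pair_stats(aln)
    if not np.isfinite(K) or K <= 0 or k_obs == 1:
        return FuFsResult(float("nan"), float("nan"), K, k_obs, aln.n)
    return fus_fs_from_counts(aln.n, k_obs, K)


@dataclass(frozen=True)
class NeutralityStats:
    D: float
    Fs: float
    constants: TajimaConstants
    theta_pi: float
    s_prime: float


def neutrality_tests(aln: MultipleAlignment) -> NeutralityStats:
    _, _, K = _pi_pair_stats(aln)
    fs = fus_fs(aln)
    return NeutralityStats(
        D=tajimas_d(aln),
        Fs=fs.Fs,
        constants=tajima_constants(max(aln.n, 2)),
        theta_pi=K,
        s_prime=fs.s_prime,
    )


# --------------------------------------------------------------------------
# Mismatch distribution
# --------------------------------------------------------------------------

def equilibrium_mismatch(d_max: int, theta: float) -> np.ndarray:
    """Constant-size expectation F(d) = theta^d / (1+theta)^(d+1)."""
    d = np.arange(d_max + 1, dtype=float)
    return np.exp(d * np.log(theta) - (d + 1) * np.log1p(theta)) if theta > 0 \
        else np.where(d == 0, 1.0, 0.0)


def expansion_mismatch(
    d_max: int, theta0: float, theta1: float, tau: float
) -> np.ndarray:
    """Sudden-expansion expectation for the pairwise difference count.

    A pair either coalesces in the post-expansion phase (population
    parameter theta1), contributing the truncated geometric term, or
    survives past the expansion tau mutational time units ago and picks up
    ~Poisson(tau) differences plus a geometric(theta0) pre-expansion
    component:

        F_j = Fhat_j(theta1) * P(j+1, tau (1 + 1/theta1))
              + exp(-tau/theta1) * sum_i Pois(j - i; tau) Fhat_i(theta0)

    with Fhat the equilibrium geometric form and P the regularised lower
    incomplete gamma function.  This is the exact closed form of the
    two-epoch model the classic intermatch literature fits.
    """
    j = np.arange(d_max + 1, dtype=float)
    fhat1 = equilibrium_mismatch(d_max, theta1)
    if theta1 > 0:
        recent = fhat1 * gammainc(j + 1, tau * (1.0 + 1.0 / theta1))
        survive = math.exp(-tau / theta1)
    else:
        recent = np.zeros_like(j)
        survive = 1.0
    fhat0 = equilibrium_mismatch(d_max, theta0)
    if tau > 0:
        log_pois = -tau + j * math.log(tau) - gammaln(j + 1)
        pois = np.exp(log_pois)
    else:
        pois = np.where(j == 0, 1.0, 0.0)
    ancient = survive * np.convolve(pois, fhat0)[: d_max + 1]
    return recent + ancient


def raggedness(rel_freq: np.ndarray) -> float:
    """Harpending's raggedness r = sum_d (f_{d+1} - f_d)^2 over the
    relative-frequency curve (with an implicit trailing zero class)."""
    f = np.concatenate([np.asarray(rel_freq, dtype=float), [0.0]])
    return float(np.sum(np.diff(f) ** 2))


@dataclass(frozen=True)
class MismatchDistribution:
    histogram: np.ndarray
    expected_constant: np.ndarray
    expected_expansion: np.ndarray
    raggedness: float
    model_params: tuple[float, float, float]  # (theta0, theta1, tau)

    @property
    def n_pairs(self) -> int:
        return int(self.histogram.sum())


# Documented fitting grid: tau spans the observed difference range, theta0
# spans [~0, 2K], theta1 the decades 1..1e4; a Nelder-Mead refinement
# starts from the best grid node.  Deterministic by construction.
_THETA1_GRID = (1.0, 10.0, 100.0, 1000.0, 10000.0)


def fit_expansion_model(
    hist: np.ndarray,
) -> tuple[float, float, float]:
    """Least-squares (theta0, theta1, tau) for the sudden-expansion curve."""
    hist = np.asarray(hist, dtype=float)
    d_max = len(hist) - 1
    obs = hist / hist.sum()
    mean_d = float(np.sum(np.arange(d_max + 1) * obs))

    def sse(theta0, theta1, tau):
        exp_ = expansion_mismatch(d_max, theta0, theta1, tau)
        return float(np.sum((obs - exp_) ** 2))

    tau_grid = np.linspace(0.0, d_max + 1.0, 33)
    theta0_grid = np.linspace(0.01, max(2.0 * mean_d, 1.0), 17)
    best = (float("inf"), (0.01, 1.0, 0.0))
    for th1 in _THETA1_GRID:
        for th0 in theta0_grid:
            for tau in tau_grid:
                v = sse(th0, th1, tau)
                if v < best[0]:
                    best = (v, (float(th0), float(th1), float(tau)))
    x0 = np.log1p(np.array(best[1]))

    def obj(x):
        th0, th1, tau = np.expm1(np.clip(x, 0.0, 25.0))
        return sse(max(th0, 1e-9), max(th1, 1e-9), max(tau, 0.0))

    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    th0, th1, tau = np.expm1(np.clip(res.x, 0.0, 25.0))
    if obj(res.x) <= best[0]:
        return float(max(th0, 1e-9)), float(max(th1, 1e-9)), float(max(tau, 0.0))
    return best[1]


def mismatch_distribution(
    aln: MultipleAlignment, fit: bool = True
) -> MismatchDistribution:
    """Observed pairwise-difference histogram with model expectations.

    Both expectation curves are renormalised over the observed class range
    and scaled to the pair count, so all three curves share one total.
    """
    if aln.n < 3:
        raise ValueError("mismatch distribution needs N >= 3")
    diffs, _ = pairwise_difference_matrix(aln)
    d = _upper(diffs)
    d_max = int(d.max())
    hist = np.bincount(d, minlength=d_max + 1).astype(float)
    n_pairs = hist.sum()
    rel = hist / n_pairs
    _, _, K = _pi_pair_stats(aln)
    const = equilibrium_mismatch(d_max, K)
    const = const / const.sum() * n_pairs if const.sum() > 0 else const
    if fit:
        th0, th1, tau = fit_expansion_model(hist)
    else:
        th0, th1, tau = K, K, 0.0
    exp_curve = expansion_mismatch(d_max, th0, th1, tau)
    s = exp_curve.sum()
    exp_curve = exp_curve / s * n_pairs if s > 0 else exp_curve
    return MismatchDistribution(
        histogram=hist,
        expected_constant=const,
        expected_expansion=exp_curve,
        raggedness=raggedness(rel),
        model_params=(th0, th1, tau),
    )


# --------------------------------------------------------------------------
# AMOVA / Phi_ST
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AmovaResult:
    ssd_among: float
    ssd_within: float
    ssd_total: float
    df_among: int
    df_within: int
    variance_among: float
    variance_within: float
    percent_among: float
    percent_within: float
    phi_st: float
    p_value: float
    n_permutations: int


def _ssd_within(dsq: np.ndarray, labels: np.ndarray, pops: np.ndarray) -> float:
    ssd = 0.0
    for p in pops:
        idx = np.flatnonzero(labels == p)
        if len(idx) < 2:
            continue
        sub = dsq[np.ix_(idx, idx)]
        ssd += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return float(ssd)


def amova(
    aln: MultipleAlignment,
    pops: PopulationMap,
    n_perm: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """One-level AMOVA on pairwise raw difference counts.

    The number of differences between two sequences is used directly as
    the squared intersequence distance (the convention of the standard
    haplotype-AMOVA software).  Negative variance components are retained
    untruncated, so percentages can fall below 0 / exceed 100.  The
    permutation p-value shuffles samples across populations and is
    observed-inclusive: p = (1 + #{Phi_perm >= Phi_obs}) / (n_perm + 1).
    """
    pops.require_complete(aln)
    labels = np.array([pops[sid] for sid in aln.ids])
    uniq = np.array(pops.populations())
    uniq = uniq[np.isin(uniq, labels)]
    P, N = len(uniq), aln.n
    if P < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    sizes = np.array([(labels == p).sum() for p in uniq], dtype=float)
    if (sizes < 2).any():
        log.warning(
            "population(s) of size 1 in AMOVA: %s",
            [p for p, s in zip(uniq, sizes) if s < 2],
        )
    diffs, _ = pairwise_difference_matrix(aln)
    dsq = diffs.astype(float)
    ssd_total = dsq[np.triu_indices(N, k=1)].sum() / N
    ssd_within = _ssd_within(dsq, labels, uniq)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = P - 1, N - P
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within
    n0 = (N - float(np.sum(sizes**2)) / N) / (P - 1)
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    total_var = var_among + var_within
    phi = var_among / total_var if total_var != 0 else float("nan")
    rng = np.random.default_rng(seed)
    count = 1  # observed included
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ssd_w = _ssd_within(dsq, perm, uniq)
        ms_a = (ssd_total - ssd_w) / df_among
        ms_w = ssd_w / df_within
        v_a = (ms_a - ms_w) / n0
        tv = v_a + ms_w
        phi_p = v_a / tv if tv != 0 else float("nan")
        if phi_p >= phi:
            count += 1
    p_value = count / (n_perm + 1)
    return AmovaResult(
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        ssd_total=ssd_total,
        df_among=df_among,
        df_within=df_within,
        variance_among=var_among,
        variance_within=var_within,
        percent_among=100.0 * var_among / total_var,
        percent_within=100.0 * var_within / total_var,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_perm,
    )


def pairwise_phi_st(
    aln: MultipleAlignment,
    pops: PopulationMap,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Pairwise Phi_ST matrix (two-population AMOVA per pair) and p-values.

    Pairs involving a population of size 1 are reported as NaN (not
    determined).  Returns a pandas DataFrame with Phi_ST below the
    diagonal mirrored above, plus a parallel p-value frame.
    """
    import pandas as pd

    labels = {sid: pops[sid] for sid in aln.ids}
    uniq = [p for p in pops.populations() if p in set(labels.values())]
    k = len(uniq)
    phi = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            ids = [s for s in aln.ids if labels[s] in (uniq[i], uniq[j])]
            sizes = [sum(1 for s in ids if labels[s] == u) for u in (uniq[i], uniq[j])]
            if min(sizes) < 2:
                continue
            sub = aln.subset(ids)
            res = amova(
                sub,
                PopulationMap({s: labels[s] for s in ids}),
                n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            phi[i, j] = phi[j, i] = res.phi_st
            pval[i, j] = pval[j, i] = res.p_value
    np.fill_diagonal(phi, 0.0)
    return (
        pd.DataFrame(phi, index=uniq, columns=uniq),
        pd.DataFrame(pval, index=uniq, columns=uniq),
    )


# --------------------------------------------------------------------------
# Principal coordinates analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PcoaResult:
    coordinates: np.ndarray      # items x axes, axes by non-increasing eigenvalue
    explained_fraction: np.ndarray
    eigenvalues: np.ndarray


def pcoa(distances: np.ndarray, atol: float = 1e-8) -> PcoaResult:
    """Classical metric scaling of a square symmetric distance matrix.

    Double-centres -D^2/2, eigendecomposes, and keeps the positive-
    eigenvalue axes; explained fractions are computed over the positive
    eigenvalues only.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=atol):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=atol):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(atol, atol * abs(vals[0]))
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    explained = vals[pos] / vals[pos].sum()
    return PcoaResult(coords, explained, vals[pos])
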