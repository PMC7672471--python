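"""EM mixture model for locating and quantifying crosslinking events.

The aligned composite is modelled as a mixture of crosslinking events.
Each event at column mu emits tags from a pair of Gaussians (sigma = 6 bp)
offset from each other by 12 bp, the + strand Gaussian to the left
(centred at mu - 6) and the - strand to the right (mu + 6); each strand's
discretised density is renormalised over the alignment span.

Components are initialised every ``init_spacing`` columns. Each EM
iteration computes per-experiment responsibilities, applies the sparse MAP
weight update pi_j = max(0, N_j - alpha) / sum_j' max(0, N_j' - alpha)
(alpha acts as the minimum tag support for an event), and moves each
component position to the argmax of the responsibility-weighted
log-likelihood summed over experiments on a grid expanding 50 bp to each
side of the previous position. Sharing one position vector across
experiments keeps event positions consistent between experiments.
Components that land on the same position are combined; components with
zero weight in every experiment are dropped.

The per-experiment input is a (2, L) array of non-negative tag weights per
strand and alignment column -- exactly the (possibly background-corrected)
composite rows, since every tag occupies a single cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TagDistributionModel",
    "EMConfig",
    "CrosslinkComponent",
    "CrosslinkMatrix",
    "EMTrace",
    "tag_likelihood",
    "em_fit",
    "quantify",
    "compare_conditions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TagDistributionModel:
    """Paired-Gaussian tag model around a crosslinking point."""

    sigma: float = 6.0
    strand_offset: float = 12.0  # + strand Gaussian sits offset/2 to the left of mu

    def strand_shift(self, strand: int) -> float:
        # strand 0 == '+': centre mu - offset/2 ; strand 1 == '-': mu + offset/2
        return -self.strand_offset / 2 if strand == 0 else self.strand_offset / 2

    def log_prob_grid(self, L: int, mus: np.ndarray, strand: int) -> np.ndarray:
        """(L, len(mus)) log probability of a tag at each column given each mu,
        renormalised over the span for each mu."""
        cols = np.arange(L, dtype=np.float64)[:, None]
        centre = np.asarray(mus, dtype=np.float64)[None, :] + self.strand_shift(strand)
        z = -((cols - centre) ** 2) / (2.0 * self.sigma**2)
        z -= _logsumexp_cols(z)
        return z

    def prob_grid(self, L: int, mus: np.ndarray, strand: int) -> np.ndarray:
        return np.exp(self.log_prob_grid(L, mus, strand))


def _logsumexp_cols(z: np.ndarray) -> np.ndarray:
    m = z.max(axis=0, keepdims=True)
    return m + np.log(np.exp(z - m).sum(axis=0, keepdims=True))


def tag_likelihood(
    tag: tuple[int, str], mu: int, model: TagDistributionModel, span: int
) -> float:
    """Probability of observing a tag (column, strand) from an event at mu,
    under the discretised paired-Gaussian model renormalised over ``span``."""
    col, strand = tag
    s = 0 if strand == "+" else 1
    p = model.prob_grid(span, np.array([mu]), s)
    return float(p[col, 0])


@dataclass(frozen=True)
class EMConfig:
    alpha: float = 20.0  # sparseness prior, in tag-count units
    init_spacing: int = 5
    mu_search_halfwidth: int = 50
    max_iterations: int = 500
    convergence_tol: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.init_spacing < 1:
            raise ValueError("init_spacing must be >= 1")


@dataclass
class CrosslinkComponent:
    mu: int  # alignment column
    pi: dict[str, float]  # per-experiment mixing weight
    N: dict[str, float]  # per-experiment responsibility mass


@dataclass
class EMTrace:
    """Per-iteration diagnostics: active positions, weight-support pattern
    and penalised observed-data log posterior."""

    iterations: list[dict] = field(default_factory=list)

    def append(self, mus, support, logpost, pi_sums):
        self.iterations.append(
            {
                "mus": tuple(mus),
                "support": tuple(map(tuple, support)),
                "logpost": logpost,
                "pi_sums": tuple(pi_sums),
            }
        )


def _log_posterior(W, pi, logP_plus, logP_minus, alpha) -> float:
    """Observed-data log likelihood plus the sparse prior term, summed over
    experiments; components with zero weight in an experiment are excluded
    from that experiment's mixture and prior."""
    total = 0.0
    for k in range(len(W)):
        act = pi[k] > 0
        if not act.any():
            continue
        for s, logP in ((0, logP_plus), (1, logP_minus)):
            w = W[k][s]
            nz = w > 0
            if not nz.any():
                continue
            mix = np.log(np.maximum(np.exp(logP[nz][:, act]) @ pi[k][act], 1e-300))
            total += float(w[nz] @ mix)
        total -= alpha * float(np.log(pi[k][act]).sum())
    return total


def em_fit(
    weights: dict[str, np.ndarray],
    cfg: EMConfig,
    model: TagDistributionModel | None = None,
    trace: EMTrace | None = None,
) -> list[CrosslinkComponent]:
    """Fit the crosslink mixture to per-experiment (2, L) tag-weight arrays.

    Returns surviving components sorted by position. Deterministic: grid
    initialisation, no randomness. Raises if no experiment has any tags.
    """
    model = model or TagDistributionModel()
    names = list(weights)
    W = [np.asarray(weights[n], dtype=np.float64) for n in names]
    if not W or any(w.ndim != 2 or w.shape[0] != 2 for w in W):
        raise ValueError("weights must map experiment -> (2, L) arrays")
    L = W[0].shape[1]
    if any(w.shape[1] != L for w in W):
        raise ValueError("all experiments must share the alignment span")
    totals = np.array([w.sum() for w in W])
    if totals.sum() <= 0:
        raise ValueError("no tags in any experiment")

    mus = np.arange(0, L, cfg.init_spacing, dtype=np.int64)
    M = len(mus)
    pi = np.full((len(W), M), 1.0 / M)
    half = cfg.mu_search_halfwidth

    for iteration in range(cfg.max_iterations):
        logP_plus = model.log_prob_grid(L, mus, 0)
        logP_minus = model.log_prob_grid(L, mus, 1)
        P = (np.exp(logP_plus), np.exp(logP_minus))

        # E-step: responsibilities per experiment, strand, column. Only the
        # per-experiment masses N and the experiment-pooled weighted
        # responsibilities (for the shared position update) are kept.
        Gsum = np.zeros((2, L, M))
        N = np.zeros((len(W), M))
        for k in range(len(W)):
            for s in (0, 1):
                num = P[s] * pi[k][None, :]
                den = num.sum(axis=1, keepdims=True)
                gamma = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
                gk = gamma * W[k][s][:, None]
                Gsum[s] += gk
                N[k] += gk.sum(axis=0)

        # MAP weight update with the sparse (negative Dirichlet) truncation
        trimmed = np.maximum(0.0, N - cfg.alpha)
        denom = trimmed.sum(axis=1, keepdims=True)
        new_pi = np.divide(trimmed, denom, out=np.zeros_like(trimmed), where=denom > 0)
        dead_rows = denom[:, 0] <= 0
        if dead_rows.all():
            j = int(np.argmax(N.sum(axis=0)))
            log.warning(
                "all components fell below alpha=%.3g; retaining the best-supported "
                "component at column %d", cfg.alpha, mus[j],
            )
            keep = np.zeros(M, dtype=bool)
            keep[j] = True
            mus, pi = mus[keep], np.ones((len(W), 1))
            break
        if dead_rows.any():
            # an experiment whose every component fell below alpha cannot
            # anchor events of its own; it keeps ML weights restricted to the
            # components that survive in the better-supported experiments
            survivors = new_pi[~dead_rows].max(axis=0) > 0
            for k in np.flatnonzero(dead_rows):
                mass = np.where(survivors, N[k], 0.0)
                if mass.sum() > 0:
                    new_pi[k] = mass / mass.sum()
                else:
                    new_pi[k] = survivors / survivors.sum()

        # shared position update: argmax of responsibility-weighted log
        # likelihood summed over experiments, on the +/- 50 bp grid
        new_mus = mus.copy()
        for j in range(M):
            if new_pi[:, j].max() <= 0:
                continue
            lo, hi = max(0, mus[j] - half), min(L - 1, mus[j] + half)
            cand = np.arange(lo, hi + 1)
            score = (
                Gsum[0, :, j] @ model.log_prob_grid(L, cand, 0)
                + Gsum[1, :, j] @ model.log_prob_grid(L, cand, 1)
            )
            best = score.max()
            winners = cand[score >= best]
            # ties resolve toward the previous position, then leftward
            new_mus[j] = winners[np.lexsort((winners, np.abs(winners - mus[j])))[0]]

        # combine components assigned identical positions
        changed_set = False
        uniq, inverse = np.unique(new_mus, return_inverse=True)
        alive = new_pi.max(axis=0) > 0
        if len(uniq) < M or not alive.all():
            merged_pi = np.zeros((len(W), len(uniq)))
            merged_N = np.zeros((len(W), len(uniq)))
            np.add.at(merged_pi.T, inverse, new_pi.T)
            np.add.at(merged_N.T, inverse, N.T)
            keep = merged_pi.max(axis=0) > 0
            mus_next, pi_next = uniq[keep], merged_pi[:, keep]
            changed_set = len(mus_next) != M or not np.array_equal(mus_next, mus)
        else:
            mus_next, pi_next = new_mus, new_pi
            changed_set = not np.array_equal(new_mus, mus)

        if trace is not None:
            lp_plus = model.log_prob_grid(L, mus_next, 0)
            lp_minus = model.log_prob_grid(L, mus_next, 1)
            trace.append(mus_next, pi_next > 0,
                         _log_posterior(W, pi_next, lp_plus, lp_minus, cfg.alpha),
                         pi_next.sum(axis=1))

        converged = (
            not changed_set
            and pi.shape == pi_next.shape
            and np.abs(pi_next - pi).sum() < cfg.convergence_tol
        )
        mus, pi, M = mus_next, pi_next, len(mus_next)
        if converged:
            break

    # final responsibilities for N under the converged parameters
    N = _responsibility_mass(W, mus, pi, model)
    components = [
        CrosslinkComponent(
            mu=int(mus[j]),
            pi={names[k]: float(pi[k, j]) for k in range(len(W))},
            N={names[k]: float(N[k, j]) for k in range(len(W))},
        )
        for j in range(len(mus))
    ]
    components.sort(key=lambda c: c.mu)
    return components


def _responsibility_mass(W, mus, pi, model) -> np.ndarray:
    L = W[0].shape[1]
    P = (model.prob_grid(L, mus, 0), model.prob_grid(L, mus, 1))
    N = np.zeros((len(W), len(mus)))
    for k in range(len(W)):
        for s in (0, 1):
            num = P[s] * pi[k][None, :]
            den = num.sum(axis=1, keepdims=True)
            gamma = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
            N[k] += (gamma * W[k][s][:, None]).sum(axis=0)
    return N


@dataclass
class CrosslinkMatrix:
    """Experiments x crosslink-position strength matrix."""

    experiments: list[str]
    positions: list[int]  # alignment columns
    raw: np.ndarray  # (K, J) expected tag counts
    normalized: np.ndarray  # rows sum to 1 (zero rows stay zero)
    zero_rows: list[str] = field(default_factory=list)

    def to_frame(self, reference_column: int = 0, normalized: bool = True) -> pd.DataFrame:
        vals = self.normalized if normalized else self.raw
        cols = [p - reference_column for p in self.positions]
        return pd.DataFrame(vals, index=self.experiments, columns=cols)

    def to_tsv(self, path, reference_column: int = 0) -> None:
        raw = self.to_frame(reference_column, normalized=False)
        norm = self.to_frame(reference_column, normalized=True)
        raw["kind"] = "raw"
        norm["kind"] = "normalized"
        pd.concat([raw, norm]).rename_axis("experiment").to_csv(path, sep="\t")


def quantify(
    components: list[CrosslinkComponent],
    weights: dict[str, np.ndarray],
    model: TagDistributionModel | None = None,
    max_iterations: int = 200,
    tol: float = 1e-9,
) -> CrosslinkMatrix:
    """Maximum-likelihood assignment of each experiment's tags to the fixed
    component positions: per-experiment EM with alpha = 0 and frozen
    positions; raw strength (k, j) is the final responsibility mass."""
    if not components:
        raise ValueError("no components to quantify")
    model = model or TagDistributionModel()
    names = list(weights)
    mus = np.array([c.mu for c in components], dtype=np.int64)
    L = next(iter(weights.values())).shape[1]
    P = (model.prob_grid(L, mus, 0), model.prob_grid(L, mus, 1))
    K, J = len(names), len(mus)
    raw = np.zeros((K, J))
    zero_rows = []
    for k, name in enumerate(names):
        w = np.asarray(weights[name], dtype=np.float64)
        if w.sum() <= 0:
            zero_rows.append(name)
            log.warning("experiment %s has no tags; zero crosslink row", name)
            continue
        pi = np.full(J, 1.0 / J)
        for _ in range(max_iterations):
            N = np.zeros(J)
            for s in (0, 1):
                num = P[s] * pi[None, :]
                den = num.sum(axis=1, keepdims=True)
                gamma = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
                N += (gamma * w[s][:, None]).sum(axis=0)
            new_pi = N / N.sum()
            if np.abs(new_pi - pi).sum() < tol:
                pi = new_pi
                break
            pi = new_pi
        raw[k] = N
    sums = raw.sum(axis=1, keepdims=True)
    normalized = np.divide(raw, sums, out=np.zeros_like(raw), where=sums > 0)
    return CrosslinkMatrix(
        experiments=names, positions=[int(m) for m in mus], raw=raw,
        normalized=normalized, zero_rows=zero_rows,
    )


def compare_conditions(
    m1: CrosslinkMatrix, m2: CrosslinkMatrix, eps: float = 1e-6
) -> pd.DataFrame:
    """Per (experiment, position) log2 fold difference of normalised
    crosslinking strengths, condition 2 over condition 1. The matrices must
    come from a joint fit (same component positions and experiments)."""
    if m1.positions != m2.positions:
        raise ValueError("crosslink matrices have mismatched component positions")
    if m1.experiments != m2.experiments:
        raise ValueError("crosslink matrices have mismatched experiments")
    fold = np.log2((m2.normalized + eps) / (m1.normalized + eps))
    return pd.DataFrame(fold, index=m1.experiments, columns=m1.positions)
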