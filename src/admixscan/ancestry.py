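"""Global ancestry proportions, local-ancestry HMM dosages, and ADD.

Local ancestry is inferred with a single-layer hidden Markov model over two
donor panels: hidden states are donor origins, emissions are Bernoulli draws
from error-adjusted panel allele frequencies, and transition probabilities
scale with ``1 - exp(-g * r * distance)`` for ``g`` generations of admixture
and per-bp recombination rate ``r``.  Phased input runs a two-state chain per
haplotype; unphased input runs a composite four-state (ordered diploid) chain
whose posteriors are collapsed to genotype dosages.  This is a deliberately
transparent surrogate for two-layer haplotype-cluster models: it is exactly
testable against exhaustive path enumeration and is sufficient for
dosage-level conclusions.

Dosages are per-haplotype-averaged, so each sample's donor dosages lie in
[0, 1] and sum to one.  The allele dosage difference (ADD) at a site is the
absolute difference between the two donors' population-mean dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)


@dataclass
class HmmConfig:
    donor_a: str
    donor_b: str
    generations: int = 100
    recomb_rate_per_bp: float = 4e-8
    epsilon: float = 0.02
    prior_a: float = 0.5
    freq_pseudocount: float = 0.5

    def validate(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")
        if not (0.0 < self.prior_a < 1.0):
            raise ValueError("prior_a must lie in (0, 1)")


@dataclass
class DosageTrack:
    """Per-sample donor-B dosage per site plus population summaries.

    Donor-A dosage is the complement, so per sample per site the dosages over
    the two donors sum to one exactly.
    """

    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: list[str]
    donor_a: str
    donor_b: str
    dosage_b: np.ndarray  # (n_sites, n_samples) in [0, 1]

    @property
    def dosage_a(self) -> np.ndarray:
        return 1.0 - self.dosage_b

    @property
    def mean_dosage_b(self) -> np.ndarray:
        return self.dosage_b.mean(axis=1)

    @property
    def mean_dosage_a(self) -> np.ndarray:
        return 1.0 - self.mean_dosage_b

    @property
    def add(self) -> np.ndarray:
        """Allele dosage difference |mean dosage_A - mean dosage_B| per site."""
        return np.abs(self.mean_dosage_a - self.mean_dosage_b)

    def to_site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                f"dosage_{self.donor_a}": self.mean_dosage_a,
                f"dosage_{self.donor_b}": self.mean_dosage_b,
                "add": self.add,
            }
        )


# ---------------------------------------------------------------------------
# Supervised global ancestry
# ---------------------------------------------------------------------------


def supervised_admixture(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    donor_panels: list[str],
    samples: list[str] | None = None,
    min_panel_samples: int = 5,
) -> pd.DataFrame:
    """Per-sample global ancestry proportions from supervised least squares.

    Finds the nonnegative, sum-to-one mixture of donor-panel allele
    frequencies closest (in squared error) to each sample's genotype dosages.
    """
    if len(donor_panels) < 2:
        raise ValueError("need at least 2 donor panels")
    freqs = []
    for pop in donor_panels:
        idx = popmap.indices(gm, pop)
        if idx.size < min_panel_samples:
            raise ValueError(f"donor panel {pop!r} has fewer than {min_panel_samples} samples")
        g = gm.genotypes[:, idx]
        tot = 2.0 * (g >= 0).sum(axis=1)
        alt = np.where(g > 0, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(tot > 0, alt / tot, np.nan))
    F = np.column_stack(freqs)  # (n_sites, n_panels)
    informative = np.isfinite(F).all(axis=1)
    if not ((F[informative] > 0) & (F[informative] < 1)).any():
        raise ValueError("donor panels monomorphic at every usable site")

    target_samples = samples or gm.sample_ids
    col = gm.sample_indices(target_samples)
    rows = []
    lam = 1e3  # weight of the sum-to-one constraint row
    for s, j in zip(target_samples, col):
        g = gm.genotypes[informative, j].astype(float)
        ok = g >= 0
        A = np.vstack([F[informative][ok], lam * np.ones(len(donor_panels))])
        y = np.concatenate([g[ok] / 2.0, [lam]])
        coef, _ = nnls(A, y)
        total = coef.sum()
        coef = coef / total if total > 0 else np.full_like(coef, 1.0 / coef.size)
        rows.append([s, *coef])
    return pd.DataFrame(rows, columns=["sample", *donor_panels]).set_index("sample")


# ---------------------------------------------------------------------------
# Local-ancestry HMM
# ---------------------------------------------------------------------------


def _panel_freqs(gm, popmap, pop, pseudocount):
    idx = popmap.indices(gm, pop)
    g = gm.genotypes[:, idx]
    tot = 2.0 * (g >= 0).sum(axis=1)
    alt = np.where(g > 0, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, (alt + pseudocount) / (tot + 2 * pseudocount), np.nan)
    return p


def _forward_backward(emit: np.ndarray, trans: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Scaled forward-backward.

    emit:  (n_sites, n_chains, n_states) emission likelihoods
    trans: (n_sites - 1, n_states, n_states) transition matrices per gap
    prior: (n_states,) initial distribution
    Returns posterior state probabilities (n_sites, n_chains, n_states).
    """
    n, m, k = emit.shape
    alpha = np.empty((n, m, k))
    scale = np.empty((n, m))
    a = prior[None, :] * emit[0]
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for t in range(1, n):
        a = (alpha[t - 1] @ trans[t - 1]) * emit[t]
        scale[t] = a.sum(axis=1)
        alpha[t] = a / scale[t][:, None]
    beta = np.empty((n, m, k))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        b = (beta[t + 1] * emit[t + 1]) @ trans[t].T
        beta[t] = b / scale[t + 1][:, None]
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


def ancestry_dosage_hmm(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    cfg: HmmConfig,
    hybrid_pop: str,
) -> DosageTrack:
    """Posterior donor dosages for every sample of ``hybrid_pop``.

    Sites where either donor panel is fully missing are excluded from the
    chain and their dosages linearly interpolated from flanking sites.
    Phased input (every site phased) decodes each haplotype independently;
    otherwise an ordered-diploid four-state chain is decoded per sample.
    """
    cfg.validate()
    pA = _panel_freqs(gm, popmap, cfg.donor_a, cfg.freq_pseudocount)
    pB = _panel_freqs(gm, popmap, cfg.donor_b, cfg.freq_pseudocount)
    usable = np.isfinite(pA) & np.isfinite(pB)
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.info("HMM skipping %d sites with missing panel frequencies", n_skipped)
    hyb_idx = popmap.indices(gm, hybrid_pop)
    sample_ids = [gm.sample_ids[i] for i in hyb_idx]

    pos_all = gm.pos
    dosage_b = np.full((gm.n_sites, hyb_idx.size), np.nan)

    eps = cfg.epsilon
    for c in dict.fromkeys(gm.chrom.tolist()):
        cmask = (gm.chrom == c) & usable
        sites = np.flatnonzero(cmask)
        if sites.size == 0:
            continue
        pos = pos_all[sites].astype(float)
        qA = (1 - eps) * pA[sites] + eps * (1 - pA[sites])
        qB = (1 - eps) * pB[sites] + eps * (1 - pB[sites])
        gaps = np.diff(pos)
        t_switch = 1.0 - np.exp(-cfg.generations * cfg.recomb_rate_per_bp * gaps)
        pi = np.array([cfg.prior_a, 1.0 - cfg.prior_a])
        # per-gap 2-state transition: stay or re-draw from the stationary prior
        T2 = np.empty((gaps.size, 2, 2))
        T2[:, 0, 0] = (1 - t_switch) + t_switch * pi[0]
        T2[:, 0, 1] = t_switch * pi[1]
        T2[:, 1, 0] = t_switch * pi[0]
        T2[:, 1, 1] = (1 - t_switch) + t_switch * pi[1]

        phased = gm.phased is not None and bool(gm.phased[sites].all()) and gm.haplotypes is not None
        if phased:
            haps = gm.haplotypes[np.ix_(sites, hyb_idx)]  # (n, s, 2)
            n, s, _ = haps.shape
            alleles = haps.reshape(n, 2 * s)
            emit = np.empty((n, 2 * s, 2))
            q = np.stack([qA, qB], axis=1)  # (n, 2)
            for st in range(2):
                e = np.where(alleles == 1, q[:, st][:, None], 1 - q[:, st][:, None])
                e = np.where(alleles < 0, 1.0, e)
                emit[:, :, st] = e
            post = _forward_backward(emit, T2, pi)
            d_b = post[:, :, 1].reshape(n, s, 2).mean(axis=2)
        else:
            g = gm.genotypes[np.ix_(sites, hyb_idx)]
            n, s = g.shape
            # ordered diploid states (h1, h2) in {A,B}^2
            pi4 = np.kron(pi, pi)
            T4 = np.einsum("gij,gkl->gikjl", T2, T2).reshape(gaps.size, 4, 4)
            emit = np.empty((n, s, 4))
            gi = np.clip(g, 0, 2)
            for si, (s1, s2) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
                p1 = qA if s1 == 0 else qB
                p2 = qA if s2 == 0 else qB
                probs = np.stack(
                    [(1 - p1) * (1 - p2), p1 * (1 - p2) + (1 - p1) * p2, p1 * p2], axis=1
                )  # (n, 3): P(genotype | ordered state)
                e = probs[np.arange(n)[:, None], gi]
                emit[:, :, si] = np.where(g >= 0, e, 1.0)
            post = _forward_backward(emit, T4, pi4)
            # dosage_B = mean count of B haplotypes: states (0,1),(1,0) carry 1/2
            d_b = post[:, :, 3] + 0.5 * (post[:, :, 1] + post[:, :, 2])
        dosage_b[sites, :] = d_b

    # interpolate skipped sites per chromosome
    for c in dict.fromkeys(gm.chrom.tolist()):
        cmask = gm.chrom == c
        cidx = np.flatnonzero(cmask)
        have = np.isfinite(dosage_b[cidx, 0])
        if have.all() or not have.any():
            if not have.any():
                dosage_b[cidx, :] = 0.5
            continue
        for j in range(hyb_idx.size):
            dosage_b[cidx[~have], j] = np.interp(
                pos_all[cidx[~have]].astype(float),
                pos_all[cidx[have]].astype(float),
                dosage_b[cidx[have], j],
            )

    return DosageTrack(
        chrom=gm.chrom.copy(),
        pos=gm.pos.copy(),
        sample_ids=sample_ids,
        donor_a=cfg.donor_a,
        donor_b=cfg.donor_b,
        dosage_b=dosage_b,
    )


def add_quantile_mask(add_values, q: float = 0.75):
    """Empirical quantile threshold (linear interpolation) and ``ADD >= threshold`` mask."""
    add = np.asarray(add_values, dtype=float)
    if add.size == 0:
        raise ValueError("empty ADD input")
    if not np.isfinite(add).all():
        raise ValueError("ADD values must be finite")
    threshold = float(np.quantile(add, q))
    return threshold, add >= threshold
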