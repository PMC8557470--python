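"""HAF-based selective-sweep scan: HAF scores, SAFE, and aggregated iSAFE.

The haplotype allele frequency (HAF) score of a haplotype is the sum, over
the derived alleles it carries, of each allele's derived count in the sample;
haplotypes riding a sweep accumulate high HAF.  For a candidate variant m in
a window,

    phi(m)   = HAF mass carried by m's carriers / total HAF mass,
    kappa(m) = distinct carrier haplotypes / distinct haplotypes,
    SAFE(m)  = (phi - kappa) / sqrt(kappa * (1 - kappa)),   0 if kappa in {0,1}.

SAFE is computed in 50%-overlapping windows of ``window_size`` variants and
aggregated into a per-variant iSAFE score:

    iSAFE(m) = rho_bar(m) * SAFE_best(m)

where rho_bar(m) is the support-weighted mean of m's normalized SAFE ranks
over the windows containing it (weights alpha_w = max(0, max SAFE in w), the
window's sweep evidence) and SAFE_best(m) is m's own strongest SAFE among
those windows.  The rank factor lies in (0, 1] and the evidence factor
inherits SAFE's calibrated scale, so neutral data stay well below the
conventional 0.1 significance line while favored variants, which top
high-evidence windows, rise far above it.  Scores are deterministic for
fixed input and invariant to sample/haplotype order.

Case/control contrast: case haplotypes are pooled with an evenly spaced
(deterministic) subsample of control haplotypes before scoring, which damps
variants shared with the controls — a variant common in both groups recruits
control carriers and its kappa rises against phi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diversity import FrequencyTable
from .io import GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)


def derived_haplotypes(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    freqs: FrequencyTable | None = None,
    outgroup: str | None = None,
    region: tuple | None = None,
):
    """Binary derived-allele haplotype matrix (n_haplotypes, n_sites) + positions.

    Requires phased input; raises otherwise (phase upstream or simulate with
    phase).  Polarization comes from a FrequencyTable (outgroup majority
    allele is ancestral) built here if not supplied.  Unpolarized sites and
    sites with missing haplotypes are dropped.
    """
    if gm.haplotypes is None or gm.phased is None or not gm.phased.all():
        raise ValueError(
            "HAF statistics require fully phased haplotypes; phase upstream or use simulated phased output"
        )
    if freqs is None:
        if outgroup is None:
            raise ValueError("need a FrequencyTable or an outgroup for polarization")
        from .diversity import allele_freqs

        freqs = allele_freqs(gm, popmap, outgroup=outgroup)
    idx = popmap.indices(gm, population)
    # derived == alt where the outgroup majority allele is ref
    o = freqs.pop_index(freqs.outgroup) if freqs.outgroup else None
    keep = freqs.polarized.copy()
    if region is not None:
        start, end = region
        keep &= (gm.pos > start) & (gm.pos <= end)
    hap = gm.haplotypes[:, idx, :].reshape(gm.n_sites, 2 * idx.size)
    keep &= (hap >= 0).all(axis=1)
    anc_is_alt = np.zeros(gm.n_sites, dtype=bool)
    if o is not None:
        anc_is_alt = np.nan_to_num(freqs.alt_freq[o]) > 0.5
    derived = np.where(anc_is_alt[:, None], 1 - hap, hap)
    return derived[keep].T.astype(np.int8), gm.pos[keep].copy()


def haf_scores(haplotypes: np.ndarray) -> np.ndarray:
    """Per-haplotype HAF: sum of sample derived counts of the carried alleles."""
    H = np.asarray(haplotypes)
    if H.ndim != 2:
        raise ValueError("expected a (haplotypes, sites) binary matrix")
    counts = H.sum(axis=0)
    return (H @ counts).astype(float)


def safe_scores(haplotypes: np.ndarray) -> pd.DataFrame:
    """Per-variant phi, kappa and SAFE within one window of phased haplotypes.

    Variants with no derived allele contribute nothing (a window whose HAF
    mass is zero yields an empty frame).
    """
    H = np.asarray(haplotypes)
    n_hap, n_var = H.shape
    haf = haf_scores(H)
    total = haf.sum()
    if total == 0:  # no derived alleles: SAFE undefined everywhere
        return pd.DataFrame(columns=["variant", "freq", "phi", "kappa", "safe"])
    uniq, inverse = np.unique(H, axis=0, return_inverse=True)
    if uniq.shape[0] < 2:
        raise ValueError("window must contain at least 2 distinct haplotypes")
    phi = (haf @ H) / total
    kappa = uniq.sum(axis=0) / uniq.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = (phi - kappa) / np.sqrt(kappa * (1 - kappa))
    safe[(kappa <= 0) | (kappa >= 1)] = 0.0
    return pd.DataFrame(
        {
            "variant": np.arange(n_var),
            "freq": H.mean(axis=0),
            "phi": phi,
            "kappa": kappa,
            "safe": safe,
        }
    )


def _windows(n_var: int, window_size: int):
    if n_var <= window_size:
        return [(0, n_var)]
    step = max(window_size // 2, 1)
    starts = list(range(0, n_var - window_size + 1, step))
    if starts[-1] + window_size < n_var:
        starts.append(n_var - window_size)
    return [(s, s + window_size) for s in starts]


def isafe_scan(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    window_size: int = 300,
    threshold: float = 0.1,
    control_haplotypes: np.ndarray | None = None,
    max_control: int | None = None,
) -> pd.DataFrame:
    """iSAFE scores over a region of phased haplotypes.

    ``window_size`` is in variants (50% overlap); a region shorter than one
    window falls back to a single window with a warning.  ``threshold`` marks
    the significance rule (strictly greater).  With ``control_haplotypes``
    the scan runs in case/control mode on the pooled matrix.
    """
    H = np.asarray(haplotypes)
    positions = np.asarray(positions)
    n_case = H.shape[0]
    weights = None
    if control_haplotypes is not None:
        C = np.asarray(control_haplotypes)
        # down-weight variants at similar frequency in the controls: a truly
        # favored introgressed allele is common in the case population and
        # rare elsewhere
        weights = np.clip(H.mean(axis=0) - C.mean(axis=0), 0.0, 1.0)
        k = max_control if max_control is not None else n_case
        if C.shape[0] > k:
            pick = np.linspace(0, C.shape[0] - 1, k).round().astype(int)
            C = C[pick]
        H = np.vstack([H, C])
    n_hap, n_var = H.shape
    if n_var == 0:
        return pd.DataFrame(columns=["pos", "freq", "phi", "kappa", "safe", "isafe", "significant"])
    if n_var < window_size:
        log.warning("region has %d variants < window of %d: single-window fallback", n_var, window_size)

    wins = _windows(n_var, window_size)
    contrib = np.zeros(n_var)
    weight_sum = np.zeros(n_var)
    best_safe = np.full(n_var, -np.inf)
    best_phi = np.full(n_var, np.nan)
    best_kappa = np.full(n_var, np.nan)
    for wi, (s, e) in enumerate(wins):
        sub = H[:, s:e]
        try:
            tab = safe_scores(sub)
        except ValueError:
            continue
        if tab.empty:
            continue
        safe = np.zeros(e - s)
        safe[tab["variant"].to_numpy()] = tab["safe"].to_numpy()
        if weights is not None:
            safe = safe * weights[s:e]
        a_w = max(float(safe.max()), 0.0)
        rho = rankdata(safe) / safe.size
        contrib[s:e] += rho * a_w
        weight_sum[s:e] += a_w
        upd = safe > best_safe[s:e]
        best_safe[s:e] = np.where(upd, safe, best_safe[s:e])
        phi_full = np.full(e - s, np.nan)
        kap_full = np.full(e - s, np.nan)
        phi_full[tab["variant"].to_numpy()] = tab["phi"].to_numpy()
        kap_full[tab["variant"].to_numpy()] = tab["kappa"].to_numpy()
        best_phi[s:e] = np.where(upd, phi_full, best_phi[s:e])
        best_kappa[s:e] = np.where(upd, kap_full, best_kappa[s:e])

    with np.errstate(invalid="ignore", divide="ignore"):
        rho_bar = np.where(weight_sum > 0, contrib / weight_sum, 0.0)
    isafe = rho_bar * np.maximum(np.where(np.isfinite(best_safe), best_safe, 0.0), 0.0)
    best_safe[~np.isfinite(best_safe)] = 0.0
    out = pd.DataFrame(
        {
            "pos": positions,
            "freq": H[:n_case].mean(axis=0),
            "phi": best_phi,
            "kappa": best_kappa,
            "safe": best_safe,
            "isafe": isafe,
            "significant": isafe > threshold,
        }
    )
    return out
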