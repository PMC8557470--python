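"""Folded-beta balancing-selection scan, shared-site intersection, bins, classification.

Long-lived balancing selection holds alleles at intermediate frequency and
lets linked neutral variants accumulate at matching frequencies, producing
clusters of SNPs whose folded frequencies track a core SNP.  The beta score
of a core SNP contrasts a similarity-weighted mutation estimate against the
neutral expectation:

    w_i    = max(0, 1 - |f_i - f_core| / maxdiff)          (triangular kernel)
    theta_B = sum of w_i over flanking SNPs within halfwidth / C_n(f_core)
    beta    = theta_B - theta_null

where C_n(f_core) is the expected kernel mass per unit theta under the
neutral folded spectrum E[eta_j] = theta * (1/j + 1/(n-j)) / (1 + [j = n-j]),
and theta_null is the genome-wide per-bp Watterson estimate scaled to the
flank window.  An isolated core SNP therefore scores negative; a cluster of
frequency-matched SNPs scores high.  Folding makes beta invariant to
allele-label flips.

Per-population p-values are one-sided normal tails of a robust Z computed
from the genome-wide median and MAD of beta (an outlier-robust summary of the
empirical genome-wide distribution), BH-corrected per population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, PopulationMap
from .utils import bh_qvalues, expand_ranges

log = logging.getLogger(__name__)


def _folded_counts(gm: GenotypeMatrix, popmap: PopulationMap, population: str):
    idx = popmap.indices(gm, population)
    if 2 * idx.size < 4:
        raise ValueError(f"population {population!r} too small for beta scan (need >= 4 haplotypes)")
    g = gm.genotypes[:, idx]
    tot = 2 * (g >= 0).sum(axis=1)
    alt = np.where(g > 0, g, 0).sum(axis=1)
    minor = np.minimum(alt, tot - alt)
    return minor, tot


def _kernel_norm(n: int, f_core: float, maxdiff: float) -> float:
    """Expected kernel mass per unit theta under the neutral folded spectrum."""
    j = np.arange(1, n // 2 + 1)
    fj = j / n
    w = np.maximum(0.0, 1.0 - np.abs(fj - f_core) / maxdiff)
    g = (1.0 / j + 1.0 / (n - j)) / np.where(2 * j == n, 2.0, 1.0)
    return float((w * g).sum())


def beta_scores(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    minfreq: float = 0.1,
    halfwidth_bp: int = 1000,
    maxdiff: float = 0.15,
) -> pd.DataFrame:
    """Per-core-site folded beta scores with robust-Z p and BH q values.

    Core SNPs are segregating sites with folded frequency >= ``minfreq``
    (the ``-fold -m`` semantics); flanking SNPs within ``halfwidth_bp``
    contribute kernel weight.
    """
    minor, tot = _folded_counts(gm, popmap, population)
    ok = (tot >= 4) & (minor > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_fold = np.where(tot > 0, minor / tot, np.nan)

    seg_idx = np.flatnonzero(ok)
    if seg_idx.size == 0:
        return pd.DataFrame(columns=["chrom", "pos", "f_core", "n_flank", "beta", "p", "q"])

    # genome-wide Watterson theta per bp from all segregating sites
    n_bar = int(np.round(tot[ok].mean()))
    a_n = float(np.sum(1.0 / np.arange(1, max(n_bar, 2))))
    span = 0
    for c in dict.fromkeys(gm.chrom.tolist()):
        p = gm.pos[gm.chrom == c]
        if p.size:
            span += int(p.max() - p.min() + 1)
    theta_bp = seg_idx.size / (a_n * max(span, 1))
    theta_null = theta_bp * 2 * halfwidth_bp

    rows = []
    for c in dict.fromkeys(gm.chrom.tolist()):
        cmask = (gm.chrom == c) & ok
        cidx = np.flatnonzero(cmask)
        if cidx.size == 0:
            continue
        pos = gm.pos[cidx]
        f = f_fold[cidx]
        n_loc = tot[cidx]
        core = f >= minfreq
        core_i = np.flatnonzero(core)
        lo = np.searchsorted(pos, pos[core_i] - halfwidth_bp, side="left")
        hi = np.searchsorted(pos, pos[core_i] + halfwidth_bp, side="right")
        rows_r, flat = expand_ranges(lo, hi)
        not_self = flat != core_i[rows_r]
        rows_r, flat = rows_r[not_self], flat[not_self]
        w = np.maximum(0.0, 1.0 - np.abs(f[flat] - f[core_i][rows_r]) / maxdiff)
        wsum = np.bincount(rows_r, weights=w, minlength=core_i.size)
        nflank = np.bincount(rows_r, minlength=core_i.size)

        # kernel normalisation per core (cache over rounded minor-count pairs)
        cache: dict = {}
        cn = np.empty(core_i.size)
        for k, ci in enumerate(core_i):
            key = (int(n_loc[ci]), round(float(f[ci]), 4))
            if key not in cache:
                cache[key] = _kernel_norm(key[0], key[1], maxdiff)
            cn[k] = cache[key]
        beta = np.where(cn > 0, wsum / np.where(cn > 0, cn, 1.0), 0.0) - theta_null

        rows.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "pos": pos[core_i],
                    "f_core": f[core_i],
                    "n_flank": nflank,
                    "beta": beta,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    b = out["beta"].to_numpy()
    med = np.median(b)
    mad = np.median(np.abs(b - med)) * 1.4826
    if mad == 0:
        mad = b.std(ddof=1) or 1.0
    z = (b - med) / mad
    out["p"] = stats.norm.sf(z)
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def shared_bs_sites(score_tables: dict, fdr: float = 0.01):
    """Intersection of per-population significant (q < fdr) balancing-selection sites.

    Tables must share a common (chrom, pos) site universe; returns the shared
    significant positions and per-population significant counts.
    """
    if len(score_tables) < 2:
        raise ValueError("need score tables for at least 2 populations")
    universes = []
    sig_sets = []
    counts = {}
    for pop, tab in score_tables.items():
        keys = set(zip(tab["chrom"], tab["pos"]))
        universes.append(keys)
        sig = set(
            zip(tab.loc[tab["q"] < fdr, "chrom"], tab.loc[tab["q"] < fdr, "pos"])
        )
        sig_sets.append(sig)
        counts[pop] = len(sig)
    common = set.intersection(*universes)
    if not common:
        raise ValueError("disjoint site universes across populations")
    shared = set.intersection(*sig_sets) & common
    counts["shared"] = len(shared)
    return sorted(shared), counts


def bs_bins(
    shared_sites,
    chrom_lengths: dict,
    window_records: pd.DataFrame | None = None,
    bin_bp: int = 10_000,
    min_sites: int = 15,
    pi_columns: list[str] | None = None,
):
    """Tile the genome in bins, count shared BS sites, flag qualifying bins.

    Returns ``(bins, summary)``: per-bin counts with a ``qualifies`` flag
    (count >= min_sites) and, when window diversity records on the same grid
    are given, a summary comparing mean pi over qualifying bins against the
    genome-wide mean.
    """
    sites = list(shared_sites)
    rows = []
    for c, length in chrom_lengths.items():
        n_bin = max(int(np.ceil(length / bin_bp)), 1)
        counts = np.zeros(n_bin, dtype=int)
        for chrom, pos in sites:
            if chrom == c:
                counts[min((int(pos) - 1) // bin_bp, n_bin - 1)] += 1
        for b in range(n_bin):
            rows.append(
                {
                    "chrom": c,
                    "start": b * bin_bp,
                    "end": min((b + 1) * bin_bp, int(length)),
                    "n_bs_sites": int(counts[b]),
                    "qualifies": bool(counts[b] >= min_sites),
                }
            )
    bins = pd.DataFrame(rows)
    summary = {"n_qualifying_bins": int(bins["qualifies"].sum())}
    if window_records is not None:
        cols = pi_columns or [c for c in window_records.columns if c.startswith("pi_")]
        merged = bins.merge(window_records, on=["chrom", "start", "end"], how="left")
        pi_all = window_records[cols].mean(axis=1)
        pi_q = merged.loc[merged["qualifies"], cols].mean(axis=1)
        summary["mean_pi_genome"] = float(pi_all.mean()) if len(pi_all) else np.nan
        summary["mean_pi_bs_bins"] = float(pi_q.mean()) if len(pi_q) else np.nan
    return bins, summary


def beta_add_classify(
    beta_table: pd.DataFrame,
    dosage_track,
    fdr: float = 0.01,
    add_min: float = 0.5,
    add_quantile: float = 0.75,
) -> pd.DataFrame:
    """Classify significant beta sites by ancestry dosage.

    Significant (q < fdr) sites with ADD >= ``add_min`` carry the strong
    single-donor signature and are donor-derived, signed by the donor with
    the larger population-mean dosage; all other significant sites are
    shared-standing variation (the genome-wide ADD ``add_quantile`` threshold
    is reported in ``attrs['add_threshold']`` for low-ADD intersection
    reports).  Sites without an ADD value are 'unscored'.
    """
    from .ancestry import add_quantile_mask

    thr, _ = add_quantile_mask(dosage_track.add, q=add_quantile)
    add_by_pos = dict(zip(zip(dosage_track.chrom, dosage_track.pos), dosage_track.add))
    mean_b = dict(zip(zip(dosage_track.chrom, dosage_track.pos), dosage_track.mean_dosage_b))

    labels = []
    for _, row in beta_table.iterrows():
        key = (row["chrom"], row["pos"])
        if not (np.isfinite(row["q"]) and row["q"] < fdr):
            labels.append("nonsignificant")
            continue
        add = add_by_pos.get(key)
        if add is None or not np.isfinite(add):
            labels.append("unscored")
            continue
        if add >= add_min:
            db = mean_b[key]
            labels.append(
                f"donor-derived-{dosage_track.donor_b}" if db >= 0.5 else f"donor-derived-{dosage_track.donor_a}"
            )
        else:
            labels.append("shared-standing")
    out = beta_table.copy()
    out["class"] = labels
    out.attrs["add_threshold"] = thr
    return out
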