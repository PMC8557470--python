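"""Per-site allele frequencies and windowed diversity statistics.

Implements the windowed scan layer shared by every downstream analysis:
per-population alternate- and derived-allele frequencies (with outgroup
polarization), nucleotide diversity pi, absolute divergence D_XY, Hudson's
F_ST as a per-window ratio of sums, and the folded site frequency spectrum.

pi and D_XY are reported per base pair using the full window length as the
denominator (positions absent from the matrix are assumed invariant), the
convention of windowed genome scans.  Hudson F_ST is not clamped: it may be
slightly negative near panmixia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PopulationMap


@dataclass
class FrequencyTable:
    """Per-site, per-population allele frequencies on a common site grid.

    ``alt_freq``/``derived_freq`` are (n_pops, n_sites); ``derived_freq`` is
    the alt frequency flipped wherever the outgroup majority allele is the
    alternate allele, and NaN at unpolarized sites.
    """

    populations: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    alt_freq: np.ndarray
    derived_freq: np.ndarray
    polarized: np.ndarray
    outgroup: str | None

    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError as e:
            raise KeyError(f"population {population!r} not in frequency table") from e


def _counts(gm: GenotypeMatrix, idx: np.ndarray):
    g = gm.genotypes[:, idx]
    nonmiss = 2 * (g >= 0).sum(axis=1)
    alt = np.where(g > 0, g, 0).sum(axis=1)
    return alt.astype(float), nonmiss.astype(float)


def allele_freqs(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    populations: list[str] | None = None,
    outgroup: str | None = None,
    outgroup_poly_max: float = 0.1,
) -> FrequencyTable:
    """Per-site alt-allele frequency per population, plus derived frequencies.

    Frequencies are computed over non-missing alleles.  If ``outgroup`` is
    given, sites where the outgroup minor-allele frequency exceeds
    ``outgroup_poly_max`` or the outgroup is fully missing are flagged
    unpolarized; elsewhere the derived frequency is the alt frequency flipped
    when the outgroup majority allele is alt.
    """
    pops = populations or popmap.populations()
    n = gm.n_sites
    alt_freq = np.full((len(pops), n), np.nan)
    for i, pop in enumerate(pops):
        idx = popmap.indices(gm, pop)  # raises if absent
        alt, tot = _counts(gm, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq[i] = np.where(tot > 0, alt / tot, np.nan)

    polarized = np.zeros(n, dtype=bool)
    derived = np.full((len(pops), n), np.nan)
    if outgroup is not None:
        o_idx = popmap.indices(gm, outgroup)
        o_alt, o_tot = _counts(gm, o_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_o = np.where(o_tot > 0, o_alt / o_tot, np.nan)
        minor = np.fmin(f_o, 1.0 - f_o)
        polarized = np.isfinite(f_o) & (minor <= outgroup_poly_max)
        anc_is_alt = f_o > 0.5
        derived = np.where(anc_is_alt[None, :], 1.0 - alt_freq, alt_freq)
        derived[:, ~polarized] = np.nan
    return FrequencyTable(
        populations=list(pops),
        chrom=gm.chrom.copy(),
        pos=gm.pos.copy(),
        alt_freq=alt_freq,
        derived_freq=derived,
        polarized=polarized,
        outgroup=outgroup,
    )


# ---------------------------------------------------------------------------
# Windowed diversity / divergence
# ---------------------------------------------------------------------------


def _window_edges(max_pos: int, window_bp: int, chrom_length: int | None):
    length = chrom_length if chrom_length is not None else int(np.ceil(max_pos / window_bp) * window_bp)
    n_win = max(int(np.ceil(length / window_bp)), 1)
    starts = np.arange(n_win) * window_bp
    ends = np.minimum(starts + window_bp, length)
    return starts, ends


def windowed_diversity(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    populations: list[str] | None = None,
    window_bp: int = 10_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Nonoverlapping windowed pi, D_XY and Hudson F_ST.

    One row per window per chromosome (0-based half-open coordinates), with
    columns ``pi_<pop>``, ``dxy_<a>__<b>`` and ``fst_<a>__<b>``.  Windows with
    no SNPs carry zeros and ``n_snps == 0``.  D_XY between a population and
    itself reduces to its pi (self-pairs excluded).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    pops = populations or popmap.populations()
    counts = {}
    for pop in pops:
        idx = popmap.indices(gm, pop)
        counts[pop] = _counts(gm, idx)

    # per-site quantities
    site_pi = {}
    for pop in pops:
        c, t = counts[pop]
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(t > 1, 2.0 * c * (t - c) / (t * (t - 1)), 0.0)
        site_pi[pop] = np.nan_to_num(pi)

    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]
    site_dxy = {}
    site_fst_num = {}
    site_fst_den = {}
    for a, b in pairs:
        c1, t1 = counts[a]
        c2, t2 = counts[b]
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.where(t1 > 0, c1 / t1, np.nan)
            p2 = np.where(t2 > 0, c2 / t2, np.nan)
            dxy = p1 * (1 - p2) + p2 * (1 - p1)
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (t1 - 1) - p2 * (1 - p2) / (t2 - 1)
        ok = np.isfinite(dxy) & (t1 > 1) & (t2 > 1)
        site_dxy[(a, b)] = np.where(ok, dxy, 0.0)
        site_fst_num[(a, b)] = np.where(ok, np.nan_to_num(num), 0.0)
        site_fst_den[(a, b)] = np.where(ok, np.nan_to_num(dxy), 0.0)

    variable = np.zeros(gm.n_sites, dtype=bool)
    for pop in pops:
        c, t = counts[pop]
        variable |= (c > 0) & (c < t)
    for a, b in pairs:
        c1, t1 = counts[a]
        c2, t2 = counts[b]
        with np.errstate(invalid="ignore", divide="ignore"):
            f1, f2 = c1 / t1, c2 / t2
        variable |= np.nan_to_num(np.abs(f1 - f2)) > 0

    rows = []
    for c in dict.fromkeys(gm.chrom.tolist()):
        cmask = gm.chrom == c
        cpos = gm.pos[cmask]
        length = (chrom_lengths or {}).get(c)
        starts, ends = _window_edges(int(cpos.max()) if cpos.size else window_bp, window_bp, length)
        widx = np.clip((cpos - 1) // window_bp, 0, len(starts) - 1)
        for w, (s, e) in enumerate(zip(starts, ends)):
            inw = np.flatnonzero(cmask)[widx == w]
            span = float(e - s)
            row = {
                "chrom": c,
                "start": int(s),
                "end": int(e),
                "n_snps": int(variable[inw].sum()),
            }
            for pop in pops:
                row[f"pi_{pop}"] = site_pi[pop][inw].sum() / span
            for a, b in pairs:
                row[f"dxy_{a}__{b}"] = site_dxy[(a, b)][inw].sum() / span
                den = site_fst_den[(a, b)][inw].sum()
                row[f"fst_{a}__{b}"] = site_fst_num[(a, b)][inw].sum() / den if den > 0 else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def dxy_self_check(gm: GenotypeMatrix, popmap: PopulationMap, population: str) -> tuple:
    """(pi, dxy) per site summed, comparing a population against itself with
    self-pairs excluded — the identity D_XY(X, X) == pi(X)."""
    idx = popmap.indices(gm, population)
    c, t = _counts(gm, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(t > 1, 2.0 * c * (t - c) / (t * (t - 1)), 0.0)
    # cross-pairs between two copies of the same sample set, minus self-pairs
    with np.errstate(invalid="ignore", divide="ignore"):
        dxy = np.where(t > 1, (2.0 * c * (t - c)) / (t * t - t), 0.0)
    return float(np.nansum(pi)), float(np.nansum(dxy))


# ---------------------------------------------------------------------------
# Folded SFS
# ---------------------------------------------------------------------------


@dataclass
class SFSRecord:
    """Folded site frequency spectrum of one population.

    ``counts[j-1]`` is the number of segregating sites with minor-allele count
    ``j`` among ``n_haplotypes`` sampled alleles; sites with missing genotypes
    in the population are dropped (``n_dropped``) and monomorphic sites are
    excluded, so ``counts.sum()`` equals the number of complete segregating
    sites.
    """

    population: str
    n_haplotypes: int
    counts: np.ndarray
    n_dropped: int


def folded_sfs(gm: GenotypeMatrix, popmap: PopulationMap, population: str) -> SFSRecord:
    idx = popmap.indices(gm, population)
    if idx.size < 2:
        raise ValueError("folded SFS requires at least 2 samples (4 haplotypes)")
    g = gm.genotypes[:, idx]
    complete = (g >= 0).all(axis=1)
    n_dropped = int((~complete).sum())
    gc = g[complete]
    n_hap = 2 * idx.size
    alt = gc.sum(axis=1)
    minor = np.minimum(alt, n_hap - alt)
    seg = (alt > 0) & (alt < n_hap)
    n_bins = n_hap // 2
    counts = np.bincount(minor[seg], minlength=n_bins + 1)[1 : n_bins + 1]
    return SFSRecord(population=population, n_haplotypes=n_hap, counts=counts, n_dropped=n_dropped)
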