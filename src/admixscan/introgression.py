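"""Four-taxon introgression scan: site patterns, windowed D / f_dM / d_f, outliers.

The scan asks whether a candidate recipient population P2 shares an excess of
derived alleles with a donor P3 relative to its sister P1, polarized by an
outgroup O.  Per-site ABBA/BABA weights use population allele frequencies
(the windowed frequency formulation rather than haplotype pattern counting):

    ABBA = (1 - p1) * p2 * p3 * (1 - pO)
    BABA = p1 * (1 - p2) * p3 * (1 - pO)

Window statistics (ratio of sums over the window's polarized sites):

* D    = sum(ABBA - BABA) / sum(ABBA + BABA)
* f_dM = sum(ABBA - BABA) / sum(dynamic-donor denominator), where the
  denominator substitutes the higher of the candidate-recipient and donor
  frequencies into both the recipient and donor slots (with a sign flip when
  P1 is the candidate recipient), giving a statistic bounded in [-1, 1] and
  antisymmetric under P1 <-> P2.
* d_f  = sum(ABBA - BABA) / sum(p3 * (1 - pO) * dxy(P1,P2)): the same
  numerator normalized by the pattern-weighted distance between P1 and P2.
  Because |p2 - p1| <= dxy(P1,P2) at every site, d_f is bounded in [-1, 1];
  it is antisymmetric under P1 <-> P2, zero when p1 = p2 everywhere, 1 for
  pure (0,1,1,0) windows, and positive under P3 -> P2 gene flow.

Outlier calling converts the chosen window statistic to genome-wide Z-scores,
one-sided normal p-values, and BH q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import FrequencyTable
from .utils import bh_qvalues

log = logging.getLogger(__name__)


@dataclass
class FourTaxonConfig:
    p1: str
    p2: str
    p3: str
    outgroup: str
    window_bp: int = 10_000
    min_biallelic_snps: int = 100

    def validate(self) -> None:
        labels = [self.p1, self.p2, self.p3, self.outgroup]
        if len(set(labels)) != 4:
            raise ValueError("P1, P2, P3 and O must be four distinct labels")


def site_patterns(freqs: FrequencyTable, cfg: FourTaxonConfig) -> pd.DataFrame:
    """Per-site ABBA/BABA weights from outgroup-polarized derived frequencies.

    Unpolarized sites (or sites with a missing frequency in any taxon) are
    excluded; the count of exclusions is attached as ``df.attrs['n_excluded']``.
    """
    cfg.validate()
    d = freqs.derived_freq
    p1 = d[freqs.pop_index(cfg.p1)]
    p2 = d[freqs.pop_index(cfg.p2)]
    p3 = d[freqs.pop_index(cfg.p3)]
    pO = d[freqs.pop_index(cfg.outgroup)]
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3) & np.isfinite(pO)
    abba = (1 - p1[ok]) * p2[ok] * p3[ok] * (1 - pO[ok])
    baba = p1[ok] * (1 - p2[ok]) * p3[ok] * (1 - pO[ok])
    df = pd.DataFrame(
        {
            "chrom": freqs.chrom[ok],
            "pos": freqs.pos[ok],
            "p1": p1[ok],
            "p2": p2[ok],
            "p3": p3[ok],
            "pO": pO[ok],
            "abba": abba,
            "baba": baba,
        }
    )
    df.attrs["n_excluded"] = int((~ok).sum())
    return df


def _fdm_denominator(p1, p2, p3, pO):
    """Dynamic-donor denominator of f_dM.

    Each site contributes the magnitude of the maximal attainable numerator
    given its recipient: max(p2, p3) substituted into the P2 and P3 slots when
    P2 is the candidate recipient (p2 >= p1), max(p1, p3) into the P1 and P3
    slots otherwise.  Contributions are nonnegative, so the window ratio is
    bounded in [-1, 1] and the statistic is antisymmetric under P1 <-> P2
    (the numerator flips sign, the denominator is invariant).
    """
    m = p2 >= p1
    pd_ = np.where(m, np.maximum(p2, p3), np.maximum(p1, p3))
    recip = np.where(m, p1, p2)
    return pd_ * (1 - pO) * (pd_ - recip)


def window_dstats(
    freqs: FrequencyTable,
    cfg: FourTaxonConfig,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Windowed D, f_dM and d_f in nonoverlapping bp windows per chromosome.

    Windows with fewer than ``cfg.min_biallelic_snps`` usable SNPs are masked
    (statistics set to NaN); zero-denominator windows are likewise NaN.
    """
    cfg.validate()
    sites = site_patterns(freqs, cfg)
    p1, p2, p3, pO = (sites[k].to_numpy() for k in ("p1", "p2", "p3", "pO"))
    num = sites["abba"].to_numpy() - sites["baba"].to_numpy()
    den_d = sites["abba"].to_numpy() + sites["baba"].to_numpy()
    den_fdm = _fdm_denominator(p1, p2, p3, pO)
    dxy12 = p1 * (1 - p2) + p2 * (1 - p1)
    den_df = p3 * (1 - pO) * dxy12
    # biallelic within the quartet: at least one taxon segregating or differing
    stacked = np.vstack([p1, p2, p3, pO])
    variable = (stacked.max(axis=0) - stacked.min(axis=0) > 0) | (
        (stacked.max(axis=0) > 0) & (stacked.min(axis=0) < 1)
    )

    rows = []
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for c in dict.fromkeys(chroms.tolist()):
        cmask = chroms == c
        cpos = pos[cmask]
        length = (chrom_lengths or {}).get(c)
        if length is None:
            length = int(np.ceil((cpos.max() if cpos.size else cfg.window_bp) / cfg.window_bp) * cfg.window_bp)
        n_win = max(int(np.ceil(length / cfg.window_bp)), 1)
        widx = np.clip((cpos - 1) // cfg.window_bp, 0, n_win - 1)
        cidx = np.flatnonzero(cmask)
        for w in range(n_win):
            inw = cidx[widx == w]
            n_snps = int(variable[inw].sum())
            row = {
                "chrom": c,
                "start": int(w * cfg.window_bp),
                "end": int(min((w + 1) * cfg.window_bp, length)),
                "n_snps": n_snps,
            }
            if n_snps < cfg.min_biallelic_snps:
                row.update({"D": np.nan, "f_dM": np.nan, "d_f": np.nan})
            else:
                s_num = num[inw].sum()
                for name, den in (("D", den_d), ("f_dM", den_fdm), ("d_f", den_df)):
                    s_den = den[inw].sum()
                    if s_den == 0:
                        row[name] = 0.0 if s_num == 0 else np.nan
                        if s_num != 0:
                            log.warning("zero %s denominator in window %s:%d", name, c, row["start"])
                    else:
                        row[name] = s_num / s_den
            rows.append(row)
    return pd.DataFrame(rows)


def outlier_windows(
    records: pd.DataFrame,
    statistic: str = "d_f",
    fdr: float = 0.05,
    direction: str = "positive",
    robust: bool = True,
) -> pd.DataFrame:
    """Genome-wide Z / one-sided p / BH q for a window statistic; flag q < fdr.

    Pools every unmasked window genome-wide for the null location and scale
    (the per-chromosome scans are combined before this step).  With
    ``robust=True`` (default) the null uses the median and MAD, which true
    outlier windows cannot inflate — on a single chromosome a strong signal
    tract would otherwise widen a mean/SD null and mask its own edges;
    ``robust=False`` uses the plain mean/SD.  Requires at least 30 unmasked
    windows for a usable null.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    out = records.copy()
    vals = out[statistic].to_numpy(dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < 30:
        raise ValueError(f"insufficient null: only {int(ok.sum())} unmasked windows (need >= 30)")
    if robust:
        mu = float(np.median(vals[ok]))
        sd = float(np.median(np.abs(vals[ok] - mu)) * 1.4826)
        if sd == 0:
            sd = vals[ok].std(ddof=1)
    else:
        mu = vals[ok].mean()
        sd = vals[ok].std(ddof=1)
    z = np.full(vals.shape, np.nan)
    p = np.full(vals.shape, np.nan)
    if sd == 0:
        log.warning("zero genome-wide SD for %s: no outliers callable", statistic)
        out["z"] = z
        out["p"] = p
        out["q"] = p
        out["outlier"] = False
        return out
    z[ok] = (vals[ok] - mu) / sd
    tail = z if direction == "positive" else -z
    p[ok] = stats.norm.sf(tail[ok])
    q = bh_qvalues(p)
    out["z"] = z
    out["p"] = p
    out["q"] = q
    out["outlier"] = np.where(np.isfinite(q), q < fdr, False)
    return out
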