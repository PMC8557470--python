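"""Genotype containers, VCF and table I/O, site-level filters and LD pruning.

Coordinate conventions used throughout the package:

* VCF site positions are 1-based (``pos``), as in the format itself.
* Window and interval coordinates are 0-based half-open (BED convention),
  so a 1-based site ``pos`` falls in the window ``[start, end)`` iff
  ``start < pos <= end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .utils import bh_qvalues

log = logging.getLogger(__name__)

MISSING = -1


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a cohort.

    ``genotypes`` holds per-sample ALT allele counts in {0, 1, 2} with -1 for
    missing, shaped (n_sites, n_samples).  ``haplotypes`` (optional) holds the
    phased allele pair per sample, shaped (n_sites, n_samples, 2) with -1 for
    missing/unphased entries; ``phased`` marks sites where every non-missing
    genotype carried a phase separator.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray | None = None
    phased: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        g = self.genotypes
        if g.shape != (self.n_sites, self.n_samples):
            raise ValueError("genotype matrix shape does not match sites x samples")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        if self.haplotypes is not None:
            h = self.haplotypes
            both = np.all(h >= 0, axis=2)
            s = h.sum(axis=2)
            ok = (~both) | (g < 0) | (s == g)
            if not np.all(ok):
                raise ValueError("genotype != sum of phased alleles at some site")

    def take(self, site_idx) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        idx = np.asarray(site_idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            genotypes=self.genotypes[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            phased=None if self.phased is None else self.phased[idx],
        )

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e} not in genotype matrix") from e


@dataclass
class PopulationMap:
    """Sample-to-population labels plus optional analysis role assignments.

    ``roles`` maps a role name (P1, P2, P3, O, donorA, donorB, hybrid...) to a
    population label; one population may carry several roles (e.g. the donor
    panel that also acts as P3 in the four-taxon test).
    """

    sample_to_pop: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == population]

    def indices(self, gm: GenotypeMatrix, population: str) -> np.ndarray:
        wanted = set(self.samples(population))
        idx = [i for i, s in enumerate(gm.sample_ids) if s in wanted]
        if not idx:
            raise KeyError(f"population {population!r} has no samples in matrix")
        return np.array(idx, dtype=np.int64)

    def population_for_role(self, role: str) -> str:
        if role not in self.roles:
            raise KeyError(f"role {role!r} not assigned")
        return self.roles[role]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.sample_ids if s not in self.sample_to_pop]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}...")
        four = [self.roles.get(r) for r in ("P1", "P2", "P3", "O")]
        four = [p for p in four if p is not None]
        if len(set(four)) != len(four):
            raise ValueError("P1, P2, P3 and O must be distinct populations")


@dataclass
class FilterConfig:
    """Site-level filter thresholds.

    max_missing_fraction: drop sites absent in more than this fraction of samples.
    min_maf: drop sites with minor allele frequency below this value.
    excess_het_fdr: drop sites whose one-sided exact heterozygote-excess test
        survives BH correction at this FDR (computed genome-wide).
    """

    max_missing_fraction: float = 0.30
    min_maf: float = 0.05
    excess_het_fdr: float = 0.01
    require_biallelic: bool = True

    def validate(self) -> None:
        for name in ("max_missing_fraction", "min_maf", "excess_het_fdr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

_BASES = {"A", "C", "G", "T"}


def _parse_region(region: str):
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    start, end = span.split("-")
    return chrom, int(start), int(end)


def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and indel/non-SNP records are dropped (counts logged).
    Phase is preserved where every non-missing call at a site uses ``|``.
    A region "chrom" or "chrom:start-end" (1-based inclusive) restricts the
    records kept; a region with no records yields an empty matrix.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as e:
        raise VcfParseError(f"cannot parse VCF {path}: {e}") from e

    want_chrom = want_start = want_end = None
    if region is not None:
        want_chrom, want_start, want_end = _parse_region(region)

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gts: list[np.ndarray] = []
    haps: list[np.ndarray] = []
    phased_sites: list[bool] = []
    dropped = {"multiallelic": 0, "non_snp": 0}

    try:
        for line_no, v in enumerate(vcf, start=1):
            if want_chrom is not None:
                if v.CHROM != want_chrom:
                    continue
                if want_start is not None and not (want_start <= v.POS <= want_end):
                    continue
            if len(v.ALT) != 1:
                dropped["multiallelic"] += 1
                continue
            if len(v.REF) != 1 or v.REF not in _BASES or len(v.ALT[0]) != 1 or v.ALT[0] not in _BASES:
                dropped["non_snp"] += 1
                continue
            calls = v.genotypes  # list of [a0, a1, phased] per sample
            site_gt = np.empty(len(samples), dtype=np.int8)
            site_hap = np.full((len(samples), 2), MISSING, dtype=np.int8)
            all_phased = True
            for i, call in enumerate(calls):
                a0, a1 = call[0], call[1]
                ph = bool(call[2]) if len(call) > 2 else False
                if a0 < 0 or a1 < 0:
                    site_gt[i] = MISSING
                else:
                    site_gt[i] = a0 + a1
                    if ph:
                        site_hap[i, 0] = a0
                        site_hap[i, 1] = a1
                    else:
                        all_phased = False
            chroms.append(v.CHROM)
            positions.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0])
            gts.append(site_gt)
            haps.append(site_hap)
            phased_sites.append(all_phased)
    except VcfParseError:
        raise
    except Exception as e:
        raise VcfParseError(f"malformed VCF {path} near record {len(positions) + 1}: {e}") from e

    if dropped["multiallelic"] or dropped["non_snp"]:
        log.info("read_vcf dropped records: %s", dropped)

    n = len(positions)
    gm = GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object) if n else np.empty(0, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        genotypes=np.vstack(gts) if n else np.empty((0, len(samples)), dtype=np.int8),
        ref=np.array(refs, dtype=object) if n else np.empty(0, dtype=object),
        alt=np.array(alts, dtype=object) if n else np.empty(0, dtype=object),
        haplotypes=np.stack(haps) if n else None,
        phased=np.array(phased_sites, dtype=bool) if n else None,
    )
    gm.drop_counts = dropped  # type: ignore[attr-defined]
    gm.validate()
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCF 4.2 text file.

    Sites flagged phased are written with ``|`` separators so that
    ``read_vcf(write_vcf(gm))`` reproduces genotypes and phase exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixscan\n")
        for c in dict.fromkeys(gm.chrom.tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        phased = gm.phased if gm.phased is not None else np.zeros(gm.n_sites, dtype=bool)
        for i in range(gm.n_sites):
            fields = [str(gm.chrom[i]), str(int(gm.pos[i])), ".", str(gm.ref[i]), str(gm.alt[i]), ".", "PASS", ".", "GT"]
            sep = "|" if phased[i] else "/"
            for j in range(gm.n_samples):
                g = gm.genotypes[i, j]
                if g < 0:
                    fields.append("./.")
                elif phased[i] and gm.haplotypes is not None:
                    a, b = gm.haplotypes[i, j]
                    fields.append(f"{a}{sep}{b}")
                else:
                    fields.append(("0/0", "0/1", "1/1")[int(g)])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------


def het_excess_pvalue(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """One-sided exact Hardy-Weinberg test for heterozygote *excess*.

    Conditions on the observed minor-allele count and sums the exact
    probabilities of all heterozygote counts at least as large as observed
    (Levene/Haldane conditional distribution).
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    # possible het counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_maj = 2 * n - n_minor
    logp = (
        hets * np.log(2)
        + gammaln(n + 1)
        - gammaln((n_minor - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_maj - hets) / 2 + 1)
        + gammaln(n_minor + 1)
        + gammaln(n_maj + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    return float(probs[hets >= n_het].sum())


def apply_site_filters(gm: GenotypeMatrix, cfg: FilterConfig | None = None):
    """Apply missingness, MAF and excess-heterozygosity filters.

    Returns ``(filtered_matrix, counts)`` where ``counts`` reports how many
    sites each rule flagged (rules are evaluated on the input matrix, so the
    counts are not mutually exclusive).  The excess-het rule is a one-sided
    exact test BH-corrected across all input sites (genome-wide).
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    if gm.n_sites == 0:
        raise ValueError("apply_site_filters requires a nonempty matrix")

    g = gm.genotypes
    miss = (g < 0).mean(axis=1)
    nonmiss = (g >= 0).sum(axis=1)
    alt = np.where(g > 0, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(nonmiss > 0, alt / (2.0 * nonmiss), np.nan)
    maf = np.fmin(f, 1.0 - f)

    bad_miss = miss > cfg.max_missing_fraction
    bad_maf = ~(maf >= cfg.min_maf)  # NaN (all-missing) fails MAF too

    n_het = (g == 1).sum(axis=1)
    n_rr = (g == 0).sum(axis=1)
    n_aa = (g == 2).sum(axis=1)
    pvals = np.array(
        [het_excess_pvalue(int(h), int(r), int(a)) for h, r, a in zip(n_het, n_rr, n_aa)]
    )
    qvals = bh_qvalues(pvals)
    bad_het = qvals < cfg.excess_het_fdr

    removed = bad_miss | bad_maf | bad_het
    counts = {
        "missingness": int(bad_miss.sum()),
        "maf": int(bad_maf.sum()),
        "excess_het": int(bad_het.sum()),
        "removed": int(removed.sum()),
        "retained": int((~removed).sum()),
    }
    if removed.all():
        log.warning("all %d sites removed by filters", gm.n_sites)
    return gm.take(np.flatnonzero(~removed)), counts


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(G: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation between genotype rows.

    G is (sites, samples) float with NaN for missing.
    """
    M = np.isfinite(G)
    Z = np.where(M, G, 0.0)
    Mf = M.astype(float)
    n = Mf @ Mf.T
    sx = Z @ Mf.T  # sum of x over jointly observed samples
    sxy = Z @ Z.T
    sxx = (Z * Z) @ Mf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var_x = n * sxx - sx**2
        r2 = cov**2 / (var_x * var_x.T)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(gm: GenotypeMatrix, window_snps: int = 100, step_snps: int = 10, r2_max: float = 0.2) -> np.ndarray:
    """Greedy left-to-right LD pruning within sliding SNP windows.

    Mirrors the classic ``--indep-pairwise`` procedure: inside each window,
    whenever a retained pair exceeds ``r2_max`` the later site (higher
    position) is dropped.  Windows never span chromosomes.  Returns the
    retained site indices (into ``gm``), deterministic for fixed input.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    G_all = gm.genotypes.astype(float)
    G_all[G_all < 0] = np.nan

    for c in dict.fromkeys(gm.chrom.tolist()):
        block = np.flatnonzero(gm.chrom == c)
        m = block.size
        for start in range(0, max(m - 1, 1), step_snps):
            widx = block[start : start + window_snps]
            widx = widx[keep[widx]]
            if widx.size < 2:
                continue
            r2 = _pairwise_r2(G_all[widx])
            alive = np.ones(widx.size, dtype=bool)
            for a in range(widx.size):
                if not alive[a]:
                    continue
                hits = (r2[a] > r2_max) & alive
                hits[: a + 1] = False
                alive[hits] = False
            keep[widx[~alive]] = False
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# Tables and maps
# ---------------------------------------------------------------------------


def write_window_table(records: pd.DataFrame, path) -> None:
    """Write a window table as BED-like TSV (0-based half-open, header line)."""
    df = pd.DataFrame(records)
    if df.empty and not list(df.columns):
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_window_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_site_table(records: pd.DataFrame, path) -> None:
    """Write a per-site table as TSV with 1-based ``pos``."""
    df = pd.DataFrame(records)
    if df.empty and not list(df.columns):
        df = pd.DataFrame(columns=["chrom", "pos"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_site_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_population_map(popmap: PopulationMap, path, roles_path=None) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.sample_to_pop.items():
            fh.write(f"{s}\t{p}\n")
    if roles_path is not None:
        with open(roles_path, "w") as fh:
            for role, pop in popmap.roles.items():
                fh.write(f"{pop}\t{role}\n")


def read_population_map(path, roles_path=None) -> PopulationMap:
    """Read ``sample<TAB>population`` (and optional ``population<TAB>role``) maps."""
    sample_to_pop: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            sample_to_pop[sample] = pop
    roles: dict[str, str] = {}
    if roles_path is not None:
        with open(roles_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                pop, role = line.split("\t")[:2]
                roles[role] = pop
    return PopulationMap(sample_to_pop=sample_to_pop, roles=roles)
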