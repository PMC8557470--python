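"""Synthetic admixed cohorts with planted introgression, sweep and balancing-selection signals.

The generator is a mosaic-frequency model, not a coalescent: population allele
frequencies diverge from a shared ancestral frequency under the
Balding-Nichols Beta model, hybrid haplotypes are Markov ancestry mosaics of
two donor populations, and the three planted signals are imposed directly:

* an introgressed tract in which most haplotypes of one hybrid population are
  forced to donor-B ancestry and homogenised around a focal derived allele
  (the sweep signature);
* clustered intermediate-frequency loci shared by every population (the
  balancing-selection signature);
* an outgroup that is fixed for the ancestral allele at most sites, so
  outgroup polarization of derived alleles can be tested against truth.

Everything the generator plants is recorded in a :class:`SimTruth` object for
parameter-recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, PopulationMap, write_population_map, write_vcf
from .utils import rng_substream

log = logging.getLogger(__name__)

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@dataclass
class HybridSpec:
    """A hybrid population: an ancestry mosaic of two donor populations.

    ``alpha`` is the stationary probability of donor-A ancestry per haplotype.
    """

    name: str
    donor_a: str
    donor_b: str
    alpha: float
    n_samples: int


@dataclass
class TractSpec:
    """Planted introgressed-and-swept tract (0-based half-open bp coordinates).

    ``carrier_freq`` is the fraction of carrier haplotypes in the carrier
    population; carriers are forced to donor-B ancestry across the tract and
    copy a near-identical core haplotype bearing the derived focal allele
    (``template_mut_rate`` is the per-site probability of deviating from it).
    """

    start: int
    end: int
    carrier_pop: str = "hybrid_north"
    carrier_freq: float = 0.95
    # carrier haplotypes copy the core haplotype but escape back to donor-pool
    # draws with probability 1 - (1 - base) * exp(-r * T * distance): the
    # hitchhiking decay of a sweep whose sojourn lasted ``sweep_generations``
    # under the cohort's recombination rate.  Escapes redraw from donor-B
    # frequencies, so local ancestry is unaffected.
    escape_base: float = 0.01
    sweep_generations: int = 25
    # the sweep is shared with the donor gene pool the tract came from: this
    # fraction of donor-B haplotypes also carries the (older, more decayed)
    # core haplotype
    donor_sweep_freq: float = 0.7
    donor_escape_base: float = 0.03
    donor_sweep_generations: int = 40


@dataclass
class BsClusterSpec:
    """Planted balancing-selection cluster: ``n_snps`` SNPs within ``width_bp``
    of ``center_bp``, all held near folded frequency ``target_freq`` in every
    donor population (hybrids inherit the intermediate frequency through the
    mosaic)."""

    center_bp: int
    n_snps: int = 35
    width_bp: int = 2000
    target_freq: float = 0.5
    jitter: float = 0.015


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the analysed system: two divergent European donor gene
    pools plus a distant outgroup, a balanced northern hybrid and a
    donor-A-dominated southern hybrid, a 400-kb introgressed sweep tract at
    4.5-4.9 Mb carried by the northern hybrid, and four 20-SNP
    balancing-selection clusters (one inside the tract, hence donor-derived).
    Mutation rate 2.5e-9 /bp/generation, 15-year generations and 100
    generations of admixture follow the study's stated values.
    """

    chrom: str = "chr10"
    chrom_length_bp: int = 5_000_000
    n_sites: int = 60_000
    donor_pops: dict = field(default_factory=lambda: {"donorA": 25, "donorB": 25})
    donor_f: dict = field(default_factory=lambda: {"donorA": 0.2, "donorB": 0.2})
    outgroup_name: str | None = "outgroup"
    n_outgroup: int = 8
    outgroup_f: float = 0.5
    outgroup_fixed_ancestral: float = 0.80
    outgroup_fixed_derived: float = 0.05
    hybrids: list = field(
        default_factory=lambda: [
            HybridSpec("hybrid_north", "donorA", "donorB", alpha=0.45, n_samples=20),
            HybridSpec("hybrid_south", "donorA", "donorB", alpha=0.60, n_samples=15),
        ]
    )
    # expected ancestry segment length = 1/switch_rate = chrom_length/20
    switch_rate_per_bp: float = 4e-6
    admixture_generations: int = 100
    recomb_rate_per_bp: float = 4e-8
    tract: TractSpec | None = field(default_factory=lambda: TractSpec(4_500_000, 4_900_000))
    bs_clusters: list = field(
        default_factory=lambda: [
            BsClusterSpec(805_000),
            BsClusterSpec(1_805_000),
            BsClusterSpec(2_805_000),
            # inside the introgressed tract but away from the sweep focus
            BsClusterSpec(4_825_000),
        ]
    )
    missing_rate: float = 0.0
    mutation_rate: float = 2.5e-9
    generation_time_years: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        for h in self.hybrids:
            if not (0.0 <= h.alpha <= 1.0):
                raise ValueError(f"hybrid {h.name}: alpha must lie in [0,1]")
            for d in (h.donor_a, h.donor_b):
                if d not in self.donor_pops:
                    raise ValueError(f"hybrid {h.name} names unknown donor {d!r}")
        for pop, f in self.donor_f.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"divergence F for {pop} must lie in (0,1)")
        if self.tract is not None:
            t = self.tract
            if not (0 <= t.start < t.end <= self.chrom_length_bp):
                raise ValueError("tract must lie within the chromosome")
            if t.carrier_pop not in {h.name for h in self.hybrids}:
                raise ValueError(f"tract carrier {t.carrier_pop!r} is not a hybrid population")
        for c in self.bs_clusters:
            half = c.width_bp // 2
            if not (0 <= c.center_bp - half and c.center_bp + half <= self.chrom_length_bp):
                raise ValueError("BS cluster extends beyond the chromosome")
            if c.n_snps > c.width_bp:
                raise ValueError("BS cluster requests more SNPs than base pairs")
        n_cluster = sum(c.n_snps for c in self.bs_clusters)
        if n_cluster > self.n_sites:
            raise ValueError("BS cluster SNPs exceed total site count")
        if self.n_sites > self.chrom_length_bp:
            raise ValueError("more sites than base pairs")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort (coordinates match output windows:
    tract is 0-based half-open; site positions are 1-based as in the VCF)."""

    chrom: str
    pos: np.ndarray
    derived_is_alt: np.ndarray
    pop_freqs: dict  # population -> true derived-allele frequency per site
    tract: tuple | None  # (start, end), 0-based half-open
    focal_pos: int | None
    bs_positions: np.ndarray
    hybrid_dosage_b: dict  # hybrid pop -> (n_samples, n_sites) true donor-B dosage
    hybrid_donors: dict  # hybrid pop -> (donor_a, donor_b)
    hybrid_sample_ids: dict
    carrier_samples: dict  # hybrid pop -> list of (sample_id, hap_index) carriers

    def dosage_sums_ok(self, tol: float = 1e-9) -> bool:
        # dosages over the two donors are stored as (d_B, 1 - d_B); verify range
        return all(
            np.all((d >= -tol) & (d <= 1 + tol)) for d in self.hybrid_dosage_b.values()
        )


def _balding_nichols(rng, p_anc: np.ndarray, f: float) -> np.ndarray:
    f = min(max(f, 1e-6), 1 - 1e-6)
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    return rng.beta(a, b)


def _markov_ancestry(rng, pos, alpha: float, n_hap: int, switch_rate: float) -> np.ndarray:
    """Per-haplotype donor-A indicator chain over sites (True = donor A).

    State re-draws from the stationary distribution occur with probability
    1 - exp(-switch_rate * distance) between consecutive sites.
    """
    n = pos.size
    if n == 0:
        return np.zeros((0, n_hap), dtype=bool)
    gaps = np.diff(pos).astype(float)
    p_redraw = 1.0 - np.exp(-switch_rate * gaps)
    redraw = np.empty((n, n_hap), dtype=bool)
    redraw[0] = True
    redraw[1:] = rng.random((n - 1, n_hap)) < p_redraw[:, None]
    candidates = rng.random((n, n_hap)) < alpha
    last = np.maximum.accumulate(np.where(redraw, np.arange(n)[:, None], 0), axis=0)
    return candidates[last, np.arange(n_hap)[None, :]]


def simulate_cohort(cfg: SimConfig | None = None):
    """Generate a phased cohort; returns ``(GenotypeMatrix, PopulationMap, SimTruth)``.

    Deterministic given ``cfg.seed``: fixed seed gives byte-identical VCF output.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = rng_substream(cfg.seed, "simulate")

    # --- site positions: random plus explicitly reserved BS cluster sites ---
    cluster_pos: list[np.ndarray] = []
    cluster_sizes: list[int] = []
    taken: set[int] = set()
    for c in cfg.bs_clusters:
        half = c.width_bp // 2
        lo, hi = c.center_bp - half + 1, c.center_bp + half  # 1-based positions
        cand = rng.choice(np.arange(lo, hi + 1), size=min(c.n_snps * 3, hi - lo + 1), replace=False)
        cand = [p for p in cand if p not in taken][: c.n_snps]
        if len(cand) < c.n_snps:
            raise ValueError("BS cluster overflow: cannot place requested SNPs")
        taken.update(cand)
        cluster_pos.append(np.array(sorted(cand), dtype=np.int64))
        cluster_sizes.append(len(cand))
    n_rand = cfg.n_sites - sum(cluster_sizes)
    cand = rng.choice(cfg.chrom_length_bp, size=min(n_rand + len(taken) + 1000, cfg.chrom_length_bp), replace=False) + 1
    # cand is in random order, so keeping the first n_rand non-reserved
    # positions is an unbiased uniform draw
    taken_arr = np.fromiter(taken, dtype=np.int64, count=len(taken))
    rand_pos = cand[~np.isin(cand, taken_arr)][:n_rand]
    if rand_pos.size < n_rand:
        raise ValueError("cannot place the requested number of sites")
    pos = np.sort(np.concatenate([rand_pos] + cluster_pos)).astype(np.int64)
    n = pos.size
    bs_mask = np.isin(pos, np.fromiter(taken, dtype=np.int64, count=len(taken)))

    # --- per-population derived-allele frequencies ---
    p_anc = rng.uniform(0.05, 0.95, size=n)
    pop_freqs: dict[str, np.ndarray] = {}
    for pop in cfg.donor_pops:
        pop_freqs[pop] = _balding_nichols(rng, p_anc, cfg.donor_f.get(pop, 0.2))
    if cfg.outgroup_name and cfg.n_outgroup > 0:
        u = rng.random(n)
        p_out = np.where(
            u < cfg.outgroup_fixed_ancestral,
            0.0,
            np.where(
                u < cfg.outgroup_fixed_ancestral + cfg.outgroup_fixed_derived,
                1.0,
                # deeply diverged outgroup: derived alleles segregate at low
                # frequency when not already fixed/lost
                _balding_nichols(rng, np.full(n, 0.15), cfg.outgroup_f),
            ),
        )
        pop_freqs[cfg.outgroup_name] = p_out

    # BS clusters: every donor population near the target folded frequency;
    # the outgroup stays fixed ancestral there so the sites remain polarizable.
    for c, cpos in zip(cfg.bs_clusters, cluster_pos):
        m = np.isin(pos, cpos)
        for pop in cfg.donor_pops:
            pop_freqs[pop][m] = np.clip(
                c.target_freq + rng.normal(0.0, c.jitter, size=m.sum()), 0.05, 0.95
            )
        if cfg.outgroup_name and cfg.n_outgroup > 0:
            pop_freqs[cfg.outgroup_name][m] = 0.0

    # --- planted tract: shared core haplotype ---
    tract_mask = None
    focal_idx = None
    template = None
    sweep_donor = None
    if cfg.tract is not None:
        t = cfg.tract
        tract_mask = (pos > t.start) & (pos <= t.end)
        in_tract = np.flatnonzero(tract_mask & ~bs_mask)
        if in_tract.size == 0:
            raise ValueError("tract contains no sites")
        mid = (t.start + t.end) // 2
        focal_idx = in_tract[np.argmin(np.abs(pos[in_tract] - mid))]
        sweep_donor = next(h.donor_b for h in cfg.hybrids if h.name == t.carrier_pop)
        # the favored mutation arose once on the swept lineage: the derived
        # focal allele is rare outside carrier haplotypes
        for pop in cfg.donor_pops:
            pop_freqs[pop][focal_idx] = 0.02
        if cfg.outgroup_name and cfg.n_outgroup > 0:
            pop_freqs[cfg.outgroup_name][focal_idx] = 0.0
        # core haplotype: a donor-B draw carrying the derived focal allele
        template = rng.random(int(tract_mask.sum())) < pop_freqs[sweep_donor][tract_mask]
        template[np.searchsorted(np.flatnonzero(tract_mask), focal_idx)] = True

    def _force_sweep(alleles: np.ndarray, carriers: np.ndarray, base: float, generations: int):
        """Overwrite carrier haplotypes in the tract with the core haplotype,
        letting sites escape back to donor-pool draws at the recombination-
        decayed rate, keeping BS-cluster sites at their planted frequencies
        and the focal derived allele on every carrier."""
        tract_local = np.flatnonzero(tract_mask)
        dist = np.abs(pos[tract_local] - pos[focal_idx]).astype(float)
        rate = 1.0 - (1.0 - base) * np.exp(-cfg.recomb_rate_per_bp * generations * dist)
        block = np.repeat(template[:, None], carriers.size, axis=1)
        esc = rng.random(block.shape) < rate[:, None]
        fresh = rng.random(block.shape) < pop_freqs[sweep_donor][tract_mask][:, None]
        block = np.where(esc, fresh, block)
        keep_bs = bs_mask[tract_mask]
        block[keep_bs] = alleles[np.ix_(tract_mask & bs_mask, carriers)]
        block[np.searchsorted(tract_local, focal_idx)] = True
        alleles[np.ix_(tract_mask, carriers)] = block

    # --- haplotypes (alleles on the derived scale) ---
    sample_ids: list[str] = []
    sample_pop: dict[str, str] = {}
    hap_cols: list[np.ndarray] = []

    def _add_pop(name: str, n_samples: int, freqs: np.ndarray):
        for k in range(n_samples):
            sid = f"{name}_{k:03d}"
            sample_ids.append(sid)
            sample_pop[sid] = name
        alleles = rng.random((n, 2 * n_samples)) < freqs[:, None]
        if (
            template is not None
            and name == sweep_donor
            and cfg.tract.donor_sweep_freq > 0
            and n_samples > 0
        ):
            n_hap = 2 * n_samples
            n_c = int(round(cfg.tract.donor_sweep_freq * n_hap))
            if n_c:
                carriers = np.sort(rng.choice(n_hap, size=n_c, replace=False))
                _force_sweep(
                    alleles, carriers, cfg.tract.donor_escape_base, cfg.tract.donor_sweep_generations
                )
        hap_cols.append(alleles)

    for pop, n_samples in cfg.donor_pops.items():
        _add_pop(pop, n_samples, pop_freqs[pop])
    if cfg.outgroup_name and cfg.n_outgroup > 0:
        _add_pop(cfg.outgroup_name, cfg.n_outgroup, pop_freqs[cfg.outgroup_name])

    hybrid_dosage_b: dict[str, np.ndarray] = {}
    hybrid_sample_ids: dict[str, list[str]] = {}
    hybrid_donors: dict[str, tuple] = {}
    carrier_samples: dict[str, list] = {}

    for h in cfg.hybrids:
        n_hap = 2 * h.n_samples
        state_a = _markov_ancestry(rng, pos, h.alpha, n_hap, cfg.switch_rate_per_bp)
        pA, pB = pop_freqs[h.donor_a], pop_freqs[h.donor_b]
        p_site = np.where(state_a, pA[:, None], pB[:, None])
        alleles = rng.random((n, n_hap)) < p_site

        if cfg.tract is not None and h.name == cfg.tract.carrier_pop:
            t = cfg.tract
            n_carrier = int(round(t.carrier_freq * n_hap))
            carriers = np.sort(rng.choice(n_hap, size=n_carrier, replace=False))
            state_a[np.ix_(tract_mask, carriers)] = False
            _force_sweep(alleles, carriers, t.escape_base, t.sweep_generations)
            carrier_samples[h.name] = [
                (f"{h.name}_{c // 2:03d}", int(c % 2)) for c in carriers
            ]

        for k in range(h.n_samples):
            sid = f"{h.name}_{k:03d}"
            sample_ids.append(sid)
            sample_pop[sid] = h.name
        hap_cols.append(alleles)
        hybrid_dosage_b[h.name] = (
            (~state_a).reshape(n, h.n_samples, 2).mean(axis=2).T.astype(float)
        )
        hybrid_sample_ids[h.name] = [f"{h.name}_{k:03d}" for k in range(h.n_samples)]
        hybrid_donors[h.name] = (h.donor_a, h.donor_b)

    haps_derived = np.concatenate(hap_cols, axis=1)  # (n_sites, 2 * n_samples_total)
    n_total = len(sample_ids)

    # --- REF/ALT assignment: derived allele is ALT at a random half of sites ---
    derived_is_alt = rng.random(n) < 0.5
    hap_alt = np.where(derived_is_alt[:, None], haps_derived, ~haps_derived)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)

    haplotypes = hap_alt.reshape(n, n_total, 2).astype(np.int8)
    genotypes = haplotypes.sum(axis=2).astype(np.int8)
    phased = np.ones(n, dtype=bool)
    if cfg.missing_rate > 0:
        drop = rng.random((n, n_total)) < cfg.missing_rate
        genotypes[drop] = -1
        haplotypes[drop] = -1
        phased = ~drop.any(axis=1)

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array([cfg.chrom] * n, dtype=object),
        pos=pos,
        genotypes=genotypes,
        ref=ref,
        alt=alt,
        haplotypes=haplotypes,
        phased=phased,
    )
    gm.validate()

    roles = {}
    donors = list(cfg.donor_pops)
    if len(donors) >= 2:
        roles["donorA"] = donors[0]
        roles["donorB"] = donors[1]
        roles["P3"] = donors[1]
    if cfg.outgroup_name and cfg.n_outgroup > 0:
        roles["O"] = cfg.outgroup_name
    if len(cfg.hybrids) >= 2:
        roles["P2"] = cfg.hybrids[0].name
        roles["P1"] = cfg.hybrids[1].name
        roles["hybrid"] = cfg.hybrids[0].name
    popmap = PopulationMap(sample_to_pop=sample_pop, roles=roles)

    truth = SimTruth(
        chrom=cfg.chrom,
        pos=pos.copy(),
        derived_is_alt=derived_is_alt,
        pop_freqs=pop_freqs,
        tract=(cfg.tract.start, cfg.tract.end) if cfg.tract else None,
        focal_pos=int(pos[focal_idx]) if focal_idx is not None else None,
        bs_positions=pos[bs_mask].copy(),
        hybrid_dosage_b=hybrid_dosage_b,
        hybrid_donors=hybrid_donors,
        hybrid_sample_ids=hybrid_sample_ids,
        carrier_samples=carrier_samples,
    )
    return gm, popmap, truth


def write_truth(truth: SimTruth, path, include_dosage: bool = True) -> None:
    obj = {
        "chrom": truth.chrom,
        "pos": truth.pos.tolist(),
        "derived_is_alt": truth.derived_is_alt.astype(int).tolist(),
        "pop_freqs": {k: np.round(v, 6).tolist() for k, v in truth.pop_freqs.items()},
        "tract": list(truth.tract) if truth.tract else None,
        "focal_pos": truth.focal_pos,
        "bs_positions": truth.bs_positions.tolist(),
        "hybrid_donors": {k: list(v) for k, v in truth.hybrid_donors.items()},
        "hybrid_sample_ids": truth.hybrid_sample_ids,
        "carrier_samples": {k: [list(x) for x in v] for k, v in truth.carrier_samples.items()},
    }
    if include_dosage:
        obj["hybrid_dosage_b"] = {
            k: np.round(v, 4).tolist() for k, v in truth.hybrid_dosage_b.items()
        }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def write_cohort(gm, popmap, truth, outdir, prefix: str = "cohort") -> dict:
    """Write VCF + population map + roles + truth JSON; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / f"{prefix}.vcf",
        "popmap": outdir / f"{prefix}.popmap.tsv",
        "roles": outdir / f"{prefix}.roles.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_vcf(gm, paths["vcf"])
    write_population_map(popmap, paths["popmap"], paths["roles"])
    write_truth(truth, paths["truth"])
    return paths


def validate_sim(gm: GenotypeMatrix, popmap: PopulationMap, truth: SimTruth) -> dict:
    """Self-consistency report for a simulated cohort.

    Checks the folded SFS shape (rare variants at least as common as
    mid-frequency ones), per-population frequency recovery against truth, and
    that true dosages lie in [0, 1] (dosages over the two donors sum to one by
    construction, as donor-A dosage is the complement of donor-B).
    """
    from .diversity import folded_sfs

    failures: list[str] = []
    if gm.n_sites == 0:
        return {"ok": False, "failures": ["no sites"], "checks": {}}
    checks: dict[str, object] = {}

    if not truth.dosage_sums_ok():
        failures.append("truth dosages outside [0,1]")

    order = {p: i for i, p in enumerate(gm.sample_ids)}
    for pop, freqs in truth.pop_freqs.items():
        try:
            idx = popmap.indices(gm, pop)
        except KeyError:
            continue
        g = gm.genotypes[:, idx]
        nonmiss = (g >= 0).sum(axis=1)
        alt = np.where(g > 0, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_alt = alt / (2.0 * nonmiss)
        f_derived = np.where(truth.derived_is_alt, f_alt, 1.0 - f_alt)
        ok = np.isfinite(f_derived)
        if ok.sum() > 2:
            r = float(np.corrcoef(f_derived[ok], freqs[ok])[0, 1])
            checks[f"freq_corr_{pop}"] = r
            if idx.size >= 20 and r <= 0.95:
                failures.append(f"frequency recovery for {pop}: corr {r:.3f} <= 0.95")
        if idx.size >= 2:
            sfs = folded_sfs(gm, popmap, pop)
            if sfs.counts.sum() > 0 and sfs.counts[0] < sfs.counts[-1]:
                failures.append(f"folded SFS shape for {pop}: singletons rarer than mid bin")
    checks["n_sites"] = gm.n_sites
    return {"ok": not failures, "failures": failures, "checks": checks}
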