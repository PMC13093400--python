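"""Synthetic study system: demography, gene dropping, and genotype emission.

Emulates a small, isolated ungulate population monitored for decades:
a drift burn-in, rapid growth to a peak, an ~83% crash, and a genetic
rescue in which outbred immigrants from a diverged source population are
translocated in over several years.  Gene dropping tracks founder
haplotype labels through recombining meioses, so every individual has a
known, exact autozygosity fraction and IBD tract list — the ground truth
against which pedigree and ROH estimators are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeDataset, MISSING
from .pedigree import (
    FEMALE,
    MALE,
    Pedigree,
    PedigreeRecord,
    UNKNOWN,
)


def _default_chrom_lengths() -> tuple[int, ...]:
    """26 autosomes summing to 2.46 Gb, sizes tapering like a real karyotype."""
    w = np.linspace(2.1, 0.55, 26)
    lens = np.round(w / w.sum() * 2.46e9).astype(np.int64)
    lens[-1] += int(2.46e9 - lens.sum())
    return tuple(int(x) for x in lens)


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    The phase schedule (piecewise-linear population targets) mirrors the
    monitored system: burn-in at ~45 animals, growth 1979-1992 to a peak,
    an 83% decline to 2002, then recovery under rescue.  35 immigrants
    arrive over 13 years (26 in 2002-2007, 9 in 2015).
    """

    seed: int = 0
    # demography
    # total-population targets (the monitored counts are ewes aged 2+;
    # totals run roughly 1.8x those)
    phases: tuple[tuple[int, int], ...] = (
        (1950, 70), (1979, 70), (1992, 200), (2002, 55), (2010, 90), (2022, 110),
    )
    rescue_schedule: dict[int, int] = field(
        default_factory=lambda: {2002: 5, 2003: 4, 2004: 4, 2005: 5, 2006: 4, 2007: 4, 2015: 9}
    )
    n_founders: int = 30
    female_breeding_ages: tuple[int, int] = (3, 12)
    male_min_age: int = 2
    max_age: int = 16
    adult_survival: float = 0.92
    male_adult_survival: float = 0.85  # rams die younger than ewes
    lamb_survival: float = 0.7
    polygyny_skew: float = 1.0  # Gamma shape; smaller = more skew
    # within-deme mate choice: sire weight scaled by
    # exp(-assortment * |immigrant ancestry of dam - of sire|), so resident
    # and introduced lineages mix gradually rather than instantaneously
    assortment: float = 2.0
    # genome / genotypes
    chrom_lengths: tuple[int, ...] = field(default_factory=_default_chrom_lengths)
    cm_per_mb: float = 1.0
    snp_per_mb: float = 15.0
    fst_source: float = 0.05
    genotyping_error: float = 0.01
    missing_rate: float = 0.02
    frac_low_qual: float = 0.03
    frac_low_depth: float = 0.03
    genotyped_from: int = 1979
    # record censoring defaults: nothing observed before the study begins;
    # between observation_start and era_start maternity comes from field
    # observation only and paternity is essentially unassignable
    observation_start: int = 1979
    era_start: int = 1987
    p_paternity_known_pre: float = 0.05
    p_maternity_known_pre: float = 0.5

    def __post_init__(self) -> None:
        if self.n_founders <= 0 or not self.chrom_lengths:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.fst_source < 1.0:
            raise ValueError("fst_source must be in [0, 1)")
        if any(l * self.snp_per_mb < 1e6 / 1e6 for l in self.chrom_lengths):
            pass  # density check below
        if min(self.chrom_lengths) * self.snp_per_mb / 1e6 < 1:
            raise ValueError("need at least one SNP per chromosome")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths))

    @classmethod
    def small(cls, seed: int = 0, **kw) -> "SimConfig":
        """Scaled-down conditions for fast end-to-end runs: same demography
        shape and rescue schedule, smaller population and a 10x smaller
        genome (held at the default SNP density)."""
        base = dict(
            seed=seed,
            phases=((1950, 35), (1979, 35), (1992, 100), (2002, 28), (2010, 45), (2022, 55)),
            chrom_lengths=tuple(int(l) for l in np.linspace(40e6, 15e6, 9)),
            n_founders=20,
            # per-capita rescue intensity matched to the full-scale schedule
            rescue_schedule={2002: 3, 2003: 2, 2004: 2, 2005: 3, 2006: 2, 2007: 2, 2015: 4},
        )
        base.update(kw)
        return cls(**base)


@dataclass
class SimTruth:
    """Exact per-individual autozygosity and IBD tracts from gene dropping."""

    table: pd.DataFrame  # individual, true_autozygosity, ancestry_class
    tracts: pd.DataFrame  # individual, chrom, start, end (1-based inclusive)
    genome_length: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# demography


class ExtinctionError(RuntimeError):
    pass


def _target_size(phases, year: int) -> int:
    ys = [p[0] for p in phases]
    ns = [p[1] for p in phases]
    return int(round(float(np.interp(year, ys, ns))))


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Year-structured pedigree following the phase schedule.

    Each year: age-dependent survival plus culling toward the target size;
    breeding females (ages 3-12) produce single offspring, sires drawn with
    polygynous (Gamma-weighted, age-increasing) skew; in rescue years the
    configured number of translocated founders joins the breeding pool.
    Deterministic under cfg.seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])
    y0, y1 = cfg.phases[0][0], cfg.phases[-1][0]
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:05d}"

    records: list[PedigreeRecord] = []
    alive: dict[str, PedigreeRecord] = {}
    q_imm: dict[str, float] = {}  # immigrant-ancestry fraction
    for _ in range(cfg.n_founders):
        r = PedigreeRecord(
            id=new_id(),
            sex=MALE if rng.random() < 0.5 else FEMALE,
            birth_year=int(y0 - rng.integers(1, 9)),
        )
        records.append(r)
        alive[r.id] = r
        q_imm[r.id] = 0.0

    for year in range(y0 + 1, y1 + 1):
        # translocations arrive first and may breed the same autumn
        for _ in range(cfg.rescue_schedule.get(year, 0)):
            age = int(rng.integers(2, 8))
            r = PedigreeRecord(
                id=new_id(),
                sex=MALE if rng.random() < 0.5 else FEMALE,
                birth_year=year - age,
                translocated=True,
                intro_year=year,
            )
            records.append(r)
            alive[r.id] = r
            q_imm[r.id] = 1.0
        # survival
        survivors: dict[str, PedigreeRecord] = {}
        for iid, r in alive.items():
            age = year - r.birth_year
            if age > cfg.max_age:
                continue
            if age <= 1:
                s = cfg.lamb_survival
            elif r.sex == MALE:
                s = cfg.male_adult_survival
            else:
                s = cfg.adult_survival
            if rng.random() < s:
                survivors[iid] = r
        target = _target_size(cfg.phases, year)
        ids = list(survivors)
        if len(ids) > target:
            drop = rng.choice(len(ids), size=len(ids) - target, replace=False)
            for k in drop:
                del survivors[ids[k]]
        alive = survivors
        females = [
            r for r in alive.values()
            if r.sex == FEMALE
            and cfg.female_breeding_ages[0] <= year - r.birth_year <= cfg.female_breeding_ages[1]
        ]
        males = [
            r for r in alive.values()
            if r.sex == MALE and year - r.birth_year >= cfg.male_min_age
        ]
        if not alive:
            raise ExtinctionError(
                f"population extinct in {year}; raise survival or targets"
            )
        n_births = min(len(females), max(0, target - len(alive)) + max(2, target // 8))
        if n_births == 0 or not males or not females:
            continue
        mothers = rng.choice(len(females), size=n_births, replace=False)
        w = rng.gamma(cfg.polygyny_skew, 1.0, size=len(males))
        w *= np.array([year - m.birth_year for m in males], dtype=float)
        q_males = np.array([q_imm[m.id] for m in males])
        for mi in mothers:
            dam = females[mi]
            wd = w * np.exp(-cfg.assortment * np.abs(q_imm[dam.id] - q_males))
            si = rng.choice(len(males), p=wd / wd.sum())
            r = PedigreeRecord(
                id=new_id(),
                sire=males[si].id,
                dam=dam.id,
                birth_year=year,
                sex=MALE if rng.random() < 0.5 else FEMALE,
            )
            records.append(r)
            alive[r.id] = r
            q_imm[r.id] = 0.5 * (q_imm[males[si].id] + q_imm[dam.id])
    return Pedigree(records)


# ---------------------------------------------------------------------------
# gene dropping

Hap = tuple[np.ndarray, np.ndarray]  # (segment start positions, founder haplotype labels)


def _recombine(hap_a: Hap, hap_b: Hap, length: int, morgans: float, rng) -> Hap:
    """One meiosis: Poisson crossovers, uniform positions, random start phase."""
    n_x = rng.poisson(morgans)
    if n_x == 0:
        src = hap_a if rng.random() < 0.5 else hap_b
        return src[0].copy(), src[1].copy()
    xs = np.sort(rng.integers(2, length + 1, size=n_x))
    bounds = np.concatenate(([1], xs, [length + 1]))
    phase = int(rng.random() < 0.5)
    starts_out: list[int] = []
    labels_out: list[int] = []
    haps = (hap_a, hap_b)
    for k in range(len(bounds) - 1):
        s, e = int(bounds[k]), int(bounds[k + 1])
        if s >= e:
            continue
        st, lb = haps[(phase + k) % 2]
        i0 = int(np.searchsorted(st, s, side="right")) - 1
        i1 = int(np.searchsorted(st, e - 1, side="right")) - 1
        for i in range(i0, i1 + 1):
            seg_start = max(s, int(st[i]))
            if labels_out and labels_out[-1] == int(lb[i]):
                continue
            starts_out.append(seg_start)
            labels_out.append(int(lb[i]))
    return np.array(starts_out, dtype=np.int64), np.array(labels_out, dtype=np.int32)


def _ibd_tracts(h1: Hap, h2: Hap, length: int) -> list[tuple[int, int]]:
    """Maximal intervals where the two homolog labels agree; 1-based inclusive."""
    s1, l1 = h1
    s2, l2 = h2
    cuts = np.union1d(s1, s2)
    i1 = np.searchsorted(s1, cuts, side="right") - 1
    i2 = np.searchsorted(s2, cuts, side="right") - 1
    eq = l1[i1] == l2[i2]
    ends = np.append(cuts[1:] - 1, length)
    tracts: list[tuple[int, int]] = []
    for k in range(len(cuts)):
        if not eq[k]:
            continue
        if tracts and tracts[-1][1] == int(cuts[k]) - 1:
            tracts[-1] = (tracts[-1][0], int(ends[k]))
        else:
            tracts.append((int(cuts[k]), int(ends[k])))
    return tracts


def gene_drop(
    ped: Pedigree, cfg: SimConfig, seed: int | None = None
) -> tuple[SimTruth, dict[str, list[list[Hap]]]]:
    """Drop founder haplotype labels through the pedigree with recombination.

    Every founder receives two unique labels; each meiosis draws a Poisson
    crossover count (no interference) from the chromosome's genetic length.
    Returns the truth table plus per-individual mosaics
    (mosaics[ind][chrom][homolog] = (starts, labels)).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed if seed is None else seed).spawn(5)[1]
    )
    lens = cfg.chrom_lengths
    morgans = [l * cfg.cm_per_mb / 1e8 for l in lens]
    genome = cfg.genome_length
    next_label = 0
    mosaics: dict[str, list[list[Hap]]] = {}
    tract_rows: list[dict] = []
    auto: dict[str, float] = {}
    for r in ped.records:
        if r.sire == UNKNOWN and r.dam == UNKNOWN:
            labs = (next_label, next_label + 1)
            next_label += 2
            mosaics[r.id] = [
                [
                    (np.array([1], dtype=np.int64), np.array([labs[0]], dtype=np.int32)),
                    (np.array([1], dtype=np.int64), np.array([labs[1]], dtype=np.int32)),
                ]
                for _ in lens
            ]
            auto[r.id] = 0.0
            continue
        # non-founder with a single recorded parent should not occur in
        # simulated pedigrees; treat the unknown side as a fresh founder
        hom: list[list[Hap]] = []
        parents = []
        for p in (r.sire, r.dam):
            if p == UNKNOWN:
                lab = next_label
                next_label += 2
                parents.append(
                    [
                        [
                            (np.array([1], dtype=np.int64), np.array([lab], dtype=np.int32)),
                            (np.array([1], dtype=np.int64), np.array([lab + 1], dtype=np.int32)),
                        ]
                        for _ in lens
                    ]
                )
            else:
                parents.append(mosaics[p])
        ibd_bp = 0
        for c, (L, M) in enumerate(zip(lens, morgans)):
            g1 = _recombine(parents[0][c][0], parents[0][c][1], L, M, rng)
            g2 = _recombine(parents[1][c][0], parents[1][c][1], L, M, rng)
            hom.append([g1, g2])
            for s, e in _ibd_tracts(g1, g2, L):
                ibd_bp += e - s + 1
                tract_rows.append(
                    {"individual": r.id, "chrom": str(c + 1), "start": s, "end": e}
                )
        mosaics[r.id] = hom
        auto[r.id] = ibd_bp / genome
    # ancestry classes
    cls: dict[str, str] = {}
    for r in ped.records:
        if r.translocated:
            cls[r.id] = "translocated"
        else:
            par_cls = [
                cls.get(p, "endemic") for p in (r.sire, r.dam) if p != UNKNOWN
            ]
            cls[r.id] = (
                "admixed"
                if any(c in ("translocated", "admixed") for c in par_cls)
                else "endemic"
            )
    table = pd.DataFrame(
        {
            "individual": [r.id for r in ped.records],
            "true_autozygosity": [auto[r.id] for r in ped.records],
            "ancestry_class": [cls[r.id] for r in ped.records],
        }
    )
    tracts = pd.DataFrame(tract_rows, columns=["individual", "chrom", "start", "end"])
    return SimTruth(table=table, tracts=tracts, genome_length=genome), mosaics


def truth_froh(truth: SimTruth, min_len: float = 1_000_000) -> pd.DataFrame:
    """Per-individual fraction of the genome in true IBD tracts >= min_len.

    The oracle for F_ROH: same length floor, same denominator (the full
    simulated genome).
    """
    t = truth.tracts
    if len(t):
        lens = (t["end"] - t["start"] + 1).to_numpy()
        keep = t[lens >= min_len]
        sums = keep.groupby("individual").apply(
            lambda g: float((g["end"] - g["start"] + 1).sum()), include_groups=False
        )
    else:
        sums = pd.Series(dtype=float)
    inds = truth.table["individual"]
    vals = inds.map(sums).fillna(0.0) / truth.genome_length
    return pd.DataFrame({"individual": inds, "true_froh": vals})


# ---------------------------------------------------------------------------
# genotype emission


def emit_genotypes(
    mosaics: dict[str, list[list[Hap]]],
    cfg: SimConfig,
    ped: Pedigree,
    seed: int | None = None,
) -> GenotypeDataset:
    """Sample SNP genotypes from the founder-haplotype mosaics.

    Endemic founder haplotypes draw alleles from ancestral frequencies
    (uniform on 0.05-0.95); translocated founder haplotypes from a
    Balding-Nichols-diverged source (F_ST = cfg.fst_source).  Per-allele
    flip error, per-genotype missingness, and QUAL/depth metadata (with a
    small planted fraction of low-QUAL / low-depth sites) make the filter
    cascade exercisable.  Individuals born before cfg.genotyped_from are
    not genotyped.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed if seed is None else seed).spawn(7)[2]
    )
    lens = cfg.chrom_lengths
    genotyped = [
        r.id
        for r in ped.records
        if r.id in mosaics
        and (r.birth_year is None or r.birth_year >= cfg.genotyped_from or r.translocated)
    ]
    # haplotype label -> source population
    tloc_labels: set[int] = set()
    for r in ped.records:
        if r.translocated and r.id in mosaics:
            for hom in mosaics[r.id][0]:
                tloc_labels.add(int(hom[1][0]))
    n_labels = 1 + max(
        int(hom[1].max()) for m in mosaics.values() for ch in m for hom in ch
    )
    site_chrom: list[str] = []
    site_pos: list[np.ndarray] = []
    hap_alleles: list[np.ndarray] = []
    for c, L in enumerate(lens):
        n_sites = max(1, int(round(L * cfg.snp_per_mb / 1e6)))
        pos = np.sort(rng.choice(np.int64(L), size=n_sites, replace=False) + 1)
        p_anc = rng.uniform(0.05, 0.95, size=n_sites)
        if cfg.fst_source > 0:
            a = p_anc * (1 - cfg.fst_source) / cfg.fst_source
            b = (1 - p_anc) * (1 - cfg.fst_source) / cfg.fst_source
            p_src = rng.beta(a, b)
        else:
            p_src = p_anc
        H = (rng.random((n_labels, n_sites)) < p_anc[None, :]).astype(np.int8)
        if tloc_labels:
            tl = np.array(sorted(tloc_labels))
            H[tl] = (rng.random((len(tl), n_sites)) < p_src[None, :]).astype(np.int8)
        site_chrom.extend([str(c + 1)] * n_sites)
        site_pos.append(pos)
        hap_alleles.append(H)
    n_total = sum(len(p) for p in site_pos)
    G = np.empty((n_total, len(genotyped)), dtype=np.int8)
    offset = 0
    for c in range(len(lens)):
        pos = site_pos[c]
        H = hap_alleles[c]
        for k, ind in enumerate(genotyped):
            a = np.zeros(len(pos), dtype=np.int8)
            for hom in mosaics[ind][c]:
                starts, labels = hom
                idx = np.searchsorted(starts, pos, side="right") - 1
                a += H[labels[idx], np.arange(len(pos))]
            G[offset : offset + len(pos), k] = a
        offset += len(pos)
    # per-allele flip error: resample each allele's flip independently
    if cfg.genotyping_error > 0:
        flips = rng.random((2, *G.shape)) < cfg.genotyping_error
        # flipping one allele moves 0<->1 or 1<->2; implement on allele pairs
        a1 = (G >= 1).astype(np.int8)  # one chromosome's allele
        a0 = (G == 2).astype(np.int8)  # the other
        a1 ^= flips[0]
        a0 ^= flips[1]
        G = (a0 + a1).astype(np.int8)
    if cfg.missing_rate > 0:
        G[rng.random(G.shape) < cfg.missing_rate] = MISSING
    qual = np.clip(rng.normal(60, 15, size=n_total), 1, None)
    low_q = rng.random(n_total) < cfg.frac_low_qual
    qual[low_q] = rng.uniform(5, 29.5, size=int(low_q.sum()))
    depth = np.clip(rng.normal(35, 6, size=n_total), 1, None)
    low_d = rng.random(n_total) < cfg.frac_low_depth
    depth[low_d] = rng.uniform(5, 19.5, size=int(low_d.sum()))
    sites = pd.DataFrame(
        {
            "chrom": site_chrom,
            "pos": np.concatenate(site_pos),
            "ref": "A",
            "alt": "G",
            "qual": qual,
            "mean_depth": depth,
            "is_snp": True,
            "is_biallelic": True,
            "hwe_p": np.nan,
        }
    )
    return GenotypeDataset(sites=sites, individuals=genotyped, genotypes=G)


def apply_record_censoring(ped: Pedigree, cfg: SimConfig, seed: int | None = None) -> Pedigree:
    """Censor the pedigree the way the records system accumulated.

    Two composed stages: before cfg.observation_start no parentage exists at
    all; between observation_start and era_start maternity is known at the
    field-observation rate and paternity at the (near-zero) pre-genotyping
    rate.  Births from era_start on keep their links.
    """
    from .pedigree import censor_records

    s = cfg.seed if seed is None else seed
    ped = censor_records(ped, cfg.observation_start, 0.0, 0.0, seed=s)
    return censor_records(
        ped, cfg.era_start, cfg.p_paternity_known_pre, cfg.p_maternity_known_pre,
        seed=s + 1,
    )


def run_simulation(cfg: SimConfig) -> tuple[Pedigree, SimTruth, GenotypeDataset]:
    """Pedigree + gene drop + genotype emission under one seed."""
    ped = simulate_pedigree(cfg)
    truth, mosaics = gene_drop(ped, cfg)
    ds = emit_genotypes(mosaics, cfg, ped)
    return ped, truth, ds
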