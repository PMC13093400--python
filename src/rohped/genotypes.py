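"""Genotype I/O, the site/individual filter cascade, and homozygosity statistics.

Genotype matrices use small integer codes: 0 = homRef, 1 = het, 2 = homAlt,
-1 = missing.  Sites are rows, individuals columns.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class FilterThresholds:
    """Defaults follow the site filter cascade applied in order:
    biallelic SNPs only, QUAL, mean depth, missingness, minor allele count,
    HWE exact test; then 100-bp window thinning."""

    drop_non_biallelic: bool = True
    min_qual: float | None = 30.0
    min_depth: float | None = 20.0
    max_missing: float | None = 0.10
    min_mac: int | None = 8
    hwe_p: float | None = 0.01
    thin_bp: int | None = 100


@dataclass
class GenotypeDataset:
    """Sites x individuals diploid genotype matrix with per-site metadata.

    ``sites`` columns: chrom, pos (1-based), ref, alt, qual, mean_depth,
    is_snp, is_biallelic, hwe_p (filled by the filter stage), alt_freq.
    """

    sites: pd.DataFrame
    individuals: list[str]
    genotypes: np.ndarray  # int8, shape (n_sites, n_individuals)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.individuals)):
            raise ValueError("genotype matrix shape does not match sites x individuals")
        if "alt_freq" not in self.sites.columns:
            self.recompute_freqs()

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def recompute_freqs(self) -> None:
        """ALT allele frequency per site from non-missing genotypes."""
        g = self.genotypes
        obs = g != MISSING
        alt = np.where(obs, g, 0).sum(axis=1)
        n = 2 * obs.sum(axis=1)
        with np.errstate(invalid="ignore"):
            self.sites = self.sites.assign(alt_freq=np.where(n > 0, alt / np.maximum(n, 1), np.nan))

    def take_sites(self, mask_or_idx) -> "GenotypeDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            individuals=list(self.individuals),
            genotypes=self.genotypes[idx],
        )

    def take_individuals(self, keep: list[str]) -> "GenotypeDataset":
        pos = [self.individuals.index(i) for i in keep]
        ds = GenotypeDataset(
            sites=self.sites.copy(),
            individuals=list(keep),
            genotypes=self.genotypes[:, pos],
        )
        ds.recompute_freqs()
        return ds


def read_vcf(path) -> GenotypeDataset:
    """Read a VCF (plain or bgzip) into a GenotypeDataset.

    Multi-allelic and indel records are retained and flagged so the filter
    stage can drop them with bookkeeping, not silently.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    rows = []
    gts = []
    for var in vcf:
        if var.format("GT") is None and var.gt_types is None:  # pragma: no cover
            raise ValueError(f"record {var.CHROM}:{var.POS} lacks a GT field")
        # gts012: 0 homRef, 1 het, 2 homAlt, 3 unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        dp = var.INFO.get("DP")
        mean_dp = float(dp) / max(len(individuals), 1) if dp is not None else np.nan
        try:
            fmt_dp = var.format("DP")
        except KeyError:
            fmt_dp = None
        if fmt_dp is not None:
            d = np.asarray(fmt_dp, dtype=float).ravel()
            mean_dp = float(np.nanmean(np.where(d < 0, np.nan, d)))
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": ",".join(var.ALT) if var.ALT else ".",
                "qual": var.QUAL if var.QUAL is not None else np.nan,
                "mean_depth": mean_dp,
                "is_snp": var.is_snp,
                "is_biallelic": len(var.ALT) == 1,
                "hwe_p": np.nan,
            }
        )
        gts.append(g)
    if not rows:
        raise ValueError(f"no records in {path}")
    sites = pd.DataFrame(rows)
    return GenotypeDataset(sites=sites, individuals=individuals, genotypes=np.array(gts, dtype=np.int8))


def write_vcf(ds: GenotypeDataset, path, source: str = "rohped") -> None:
    """Write the dataset as a plain-text VCF 4.2 with QUAL/INFO DP/GT."""
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom in pd.unique(ds.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ds.individuals) + "\n")
        n = ds.n_individuals
        for k, site in enumerate(ds.sites.itertuples(index=False)):
            dp_total = int(round((site.mean_depth if math.isfinite(site.mean_depth) else 0) * n))
            cells = "\t".join(gt_str[int(g)] for g in ds.genotypes[k])
            qual = f"{site.qual:.1f}" if math.isfinite(site.qual) else "."
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t{qual}\t.\tDP={dp_total}\tGT\t{cells}\n"
            )


# ---------------------------------------------------------------------------
# HWE exact test

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the conditional probabilities (given allele counts) of every
    heterozygote count whose probability does not exceed that of the observed
    count, using the standard recurrence over heterozygote counts.
    Monomorphic sites return 1.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare allele count
    het_obs = n_het
    hets = list(range(n_rare % 2, n_rare + 1, 2))
    # unnormalized probabilities via the recurrence
    # P(h+2)/P(h) = 4*hr*ha / ((h+2)*(h+1)) with hr, ha the hom counts at h
    probs = {}
    h_mid = hets[len(hets) // 2]
    probs[h_mid] = 1.0
    def homs(h):
        hr = (n_rare - h) // 2
        ha = n - hr - h
        return hr, ha
    for h in range(h_mid, hets[-1], 2):
        hr, ha = homs(h)
        probs[h + 2] = probs[h] * 4.0 * hr * ha / ((h + 2.0) * (h + 1.0))
    for h in range(h_mid, hets[0], -2):
        hr, ha = homs(h)
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hr + 1.0) * (ha + 1.0))
    total = sum(probs.values())
    p_obs = probs[het_obs] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# filter cascade

@dataclass
class FilterReport:
    """Sites removed per criterion, in application order."""

    removed: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps(
            {"n_input": self.n_input, "removed": self.removed, "n_output": self.n_output},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def filter_sites(
    ds: GenotypeDataset, cfg: FilterThresholds | None = None
) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the ordered site filter cascade, then 100-bp thinning.

    Order: non-biallelic/indel, QUAL, mean depth, per-site missingness,
    minor allele count, HWE exact test; finally greedy physical-distance
    thinning so no two retained sites on a chromosome lie within ``thin_bp``.
    The report counts removals per criterion in that order.
    """
    cfg = cfg or FilterThresholds()
    rep = FilterReport(n_input=ds.n_sites)
    cur = ds

    def apply(name: str, keep: np.ndarray) -> None:
        nonlocal cur
        rep.removed[name] = int((~keep).sum())
        cur = cur.take_sites(keep)

    if cfg.drop_non_biallelic:
        apply("non_biallelic_or_indel",
              (cur.sites["is_snp"] & cur.sites["is_biallelic"]).to_numpy())
    if cfg.min_qual is not None:
        apply("qual", (cur.sites["qual"].to_numpy() >= cfg.min_qual))
    if cfg.min_depth is not None:
        apply("depth", (cur.sites["mean_depth"].to_numpy() >= cfg.min_depth))
    if cfg.max_missing is not None:
        miss = (cur.genotypes == MISSING).mean(axis=1)
        apply("missingness", miss <= cfg.max_missing)
    if cfg.min_mac is not None:
        g = cur.genotypes
        obs = g != MISSING
        alt = np.where(obs, g, 0).sum(axis=1)
        tot = 2 * obs.sum(axis=1)
        mac = np.minimum(alt, tot - alt)
        apply("mac", mac >= cfg.min_mac)
    if cfg.hwe_p is not None:
        g = cur.genotypes
        pvals = np.array(
            [
                hwe_exact_test(
                    int((row == HOM_REF).sum()),
                    int((row == HET).sum()),
                    int((row == HOM_ALT).sum()),
                )
                if (row != MISSING).any()
                else 1.0
                for row in g
            ]
        )
        cur.sites = cur.sites.assign(hwe_p=pvals)
        apply("hwe", pvals >= cfg.hwe_p)
    if cfg.thin_bp is not None and cur.n_sites:
        # greedy distance thinning: keep a site only if it lies at least
        # thin_bp beyond the previously kept site on the same chromosome
        pos = cur.sites["pos"].to_numpy()
        chroms = cur.sites["chrom"].to_numpy()
        keep = np.zeros(cur.n_sites, dtype=bool)
        last_chrom, last_pos = None, None
        for i in range(cur.n_sites):
            if chroms[i] != last_chrom or pos[i] - last_pos >= cfg.thin_bp:
                keep[i] = True
                last_chrom, last_pos = chroms[i], pos[i]
        apply("thin", keep)
    if cur.n_sites == 0:
        warnings.warn("filter cascade removed every site", stacklevel=2)
    cur.recompute_freqs()
    rep.n_output = cur.n_sites
    return cur, rep


def filter_individuals(ds: GenotypeDataset, max_missing: float = 0.25) -> GenotypeDataset:
    """Drop individuals with more than ``max_missing`` missing genotypes."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    miss = (ds.genotypes == MISSING).mean(axis=0)
    keep = [i for i, m in zip(ds.individuals, miss) if m <= max_missing]
    if not keep:
        raise ValueError("individual missingness filter removed every individual")
    return ds.take_individuals(keep)


# ---------------------------------------------------------------------------
# homozygosity statistics

@dataclass
class HetStats:
    """Per-individual observed/expected homozygosity and F_IS."""

    table: pd.DataFrame  # columns: individual, o_hom, e_hom, f_is, n_sites

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def het_stats(ds: GenotypeDataset) -> HetStats:
    """O_hom, E_hom (HWE expectation from cohort frequencies) and F_IS.

    E_hom for an individual averages p^2 + q^2 over its non-missing sites;
    F_IS = (O_hom - E_hom) / (1 - E_hom).  Individuals with no non-missing
    sites get NaN throughout.
    """
    g = ds.genotypes
    obs = g != MISSING
    hom = (g == HOM_REF) | (g == HOM_ALT)
    p = ds.sites["alt_freq"].to_numpy()
    ehom_site = p**2 + (1 - p) ** 2
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        o_hom = np.where(n > 0, (hom & obs).sum(axis=0) / np.maximum(n, 1), np.nan)
        e_hom = np.where(
            n > 0,
            (obs * ehom_site[:, None]).sum(axis=0) / np.maximum(n, 1),
            np.nan,
        )
        f_is = np.where(e_hom < 1, (o_hom - e_hom) / (1 - e_hom), np.nan)
    return HetStats(
        table=pd.DataFrame(
            {
                "individual": ds.individuals,
                "o_hom": o_hom,
                "e_hom": e_hom,
                "f_is": f_is,
                "n_sites": n.astype(int),
            }
        )
    )


def flag_ascertainment_outliers(stats: HetStats, f_is_threshold: float = -0.3) -> list[str]:
    """Individuals whose F_IS falls below the (negative) threshold.

    Such strongly negative values indicate SNP-panel ascertainment toward
    loci heterozygous in particular animals; flagged individuals are excluded
    from homozygosity/F_IS summaries but kept for ROH calling, which relies
    on extended tracts and is far less sensitive to ascertainment.
    """
    t = stats.table
    return t.loc[t["f_is"] < f_is_threshold, "individual"].tolist()
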