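"""Two-state autozygosity HMM over hard genotype calls and allele frequencies.

States are HW (non-autozygous: genotypes drawn from Hardy-Weinberg
proportions) and AZ (autozygous: both homologs identical by descent, so
heterozygotes arise only through genotyping error).  Transition
probabilities between adjacent sites depend on physical distance d through
per-base-pair switch rates: P(switch) = 1 - exp(-rate * d) per direction.
Chromosomes are decoded independently, starting from the stationary state
distribution.  Viterbi decoding defines ROH segments; forward-backward
posteriors are kept for QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeDataset, MISSING

STATE_HW, STATE_AZ = 0, 1

#: autosomal genome length used as the F_ROH denominator (bp)
DEFAULT_L_AUTO = 2.46e9
DEFAULT_MIN_LEN = 1_000_000
#: ROH length bins in bp: [1, 5] Mb, (5, 20] Mb, (20, inf) Mb
DEFAULT_BINS = ((1_000_000, 5_000_000), (5_000_000, 20_000_000), (20_000_000, np.inf))
BIN_LABELS = ("froh_1to5", "froh_5to20", "froh_gt20")


@dataclass
class HmmParams:
    """h2a / a2h are per-bp switch rates HW->AZ and AZ->HW (the cited ROH
    caller's documented defaults); eps is the genotyping error rate used by
    the emission model."""

    h2a: float = 6.7e-8
    a2h: float = 5e-9
    eps: float = 0.01
    min_gq: float | None = None

    def __post_init__(self) -> None:
        if self.h2a <= 0 or self.a2h <= 0:
            raise ValueError("transition rates must be positive")
        if not 0.0 < self.eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")

    @property
    def stationary_az(self) -> float:
        return self.h2a / (self.h2a + self.a2h)


def emission_probs(genotype: int, alt_freq: float, eps: float) -> tuple[float, float]:
    """(P(g | HW), P(g | AZ)) for one genotype code at one site.

    HW: Hardy-Weinberg genotype proportions pushed through a per-allele
    flip-error confusion matrix.  AZ: the underlying IBD allele is ref with
    probability 1-p and alt with probability p; a heterozygote can only be
    produced by error, with probability eps.  Missing genotypes are
    uninformative: both likelihoods 1.
    """
    if genotype == MISSING:
        return 1.0, 1.0
    p = float(alt_freq)
    q = 1.0 - p
    hw = _hw_emission_row(p, eps)
    az = (q * (1 - eps), eps, p * (1 - eps))
    return float(hw[genotype]), float(az[genotype])


def _confusion(eps: float) -> np.ndarray:
    """True-genotype -> observed-genotype matrix under independent allele flips."""
    e, f = eps, 1.0 - eps
    return np.array(
        [
            [f * f, 2 * e * f, e * e],
            [e * f, f * f + e * e, e * f],
            [e * e, 2 * e * f, f * f],
        ]
    )


def _hw_emission_row(p: float, eps: float) -> np.ndarray:
    q = 1.0 - p
    hwe = np.array([q * q, 2 * p * q, p * p])
    return hwe @ _confusion(eps)


def _site_emissions(G: np.ndarray, p: np.ndarray, eps: float) -> np.ndarray:
    """Emission likelihoods, shape (n_sites, n_ind, 2); missing -> (1, 1)."""
    n_sites, n_ind = G.shape
    q = 1.0 - p
    C = _confusion(eps)
    hwe = np.stack([q * q, 2 * p * q, p * p], axis=1)  # (n_sites, 3)
    hw_rows = hwe @ C  # (n_sites, 3) per observed genotype
    az_rows = np.stack([q * (1 - eps), np.full_like(p, eps), p * (1 - eps)], axis=1)
    out = np.ones((n_sites, n_ind, 2))
    obs = G != MISSING
    gi = np.where(obs, G, 0)
    rows = np.arange(n_sites)[:, None]
    out[..., STATE_HW] = np.where(obs, hw_rows[rows, gi], 1.0)
    out[..., STATE_AZ] = np.where(obs, az_rows[rows, gi], 1.0)
    return out


def _gap_log_trans(positions: np.ndarray, params: HmmParams) -> np.ndarray:
    """log transition matrices for each inter-site gap, shape (n_sites-1, 2, 2)."""
    d = np.diff(positions.astype(float))
    p_ha = -np.expm1(-params.h2a * d)  # HW -> AZ
    p_ah = -np.expm1(-params.a2h * d)  # AZ -> HW
    T = np.empty((len(d), 2, 2))
    T[:, STATE_HW, STATE_HW] = 1 - p_ha
    T[:, STATE_HW, STATE_AZ] = p_ha
    T[:, STATE_AZ, STATE_HW] = p_ah
    T[:, STATE_AZ, STATE_AZ] = 1 - p_ah
    with np.errstate(divide="ignore"):
        return np.log(T)


def decode_chromosome(
    G: np.ndarray, positions: np.ndarray, alt_freq: np.ndarray, params: HmmParams
) -> tuple[np.ndarray, np.ndarray]:
    """Viterbi paths and AZ posteriors for all individuals of one chromosome.

    G is (n_sites, n_ind) genotype codes at sites sorted by position.
    Returns (paths, posterior_az), both (n_sites, n_ind); paths hold state
    codes, ties in the Viterbi backtrace resolve to HW.
    """
    n_sites, n_ind = G.shape
    order = np.argsort(positions, kind="stable")
    if not np.array_equal(order, np.arange(n_sites)):
        raise ValueError("sites must be sorted by position")
    emis = _site_emissions(G, alt_freq, params.eps)
    with np.errstate(divide="ignore"):
        log_emis = np.log(emis)
        log_pi = np.log(
            np.array([1.0 - params.stationary_az, params.stationary_az])
        )
    logT = _gap_log_trans(positions, params)

    # Viterbi
    delta = log_pi[None, :] + log_emis[0]  # (n_ind, 2)
    back = np.empty((n_sites, n_ind, 2), dtype=np.int8)
    back[0] = 0
    for t in range(1, n_sites):
        cand = delta[:, :, None] + logT[t - 1][None, :, :]  # (n_ind, from, to)
        back[t] = np.argmax(cand, axis=1)  # ties -> HW (lower index)
        delta = np.take_along_axis(cand, back[t][:, None, :], axis=1)[:, 0, :] + log_emis[t]
    paths = np.empty((n_sites, n_ind), dtype=np.int8)
    paths[-1] = np.argmax(delta, axis=1)
    for t in range(n_sites - 2, -1, -1):
        paths[t] = np.take_along_axis(back[t + 1], paths[t + 1][:, None], axis=1)[:, 0]

    # forward-backward with per-site scaling
    T = np.exp(logT)
    pi = np.exp(log_pi)
    alpha = np.empty((n_sites, n_ind, 2))
    scale = np.empty((n_sites, n_ind))
    a = pi[None, :] * emis[0]
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for t in range(1, n_sites):
        a = np.einsum("if,ft->it", alpha[t - 1], T[t - 1]) * emis[t]
        scale[t] = a.sum(axis=1)
        alpha[t] = a / scale[t][:, None]
    beta = np.empty_like(alpha)
    beta[-1] = 1.0
    for t in range(n_sites - 2, -1, -1):
        b = np.einsum("ft,it->if", T[t], emis[t + 1] * beta[t + 1])
        beta[t] = b / scale[t + 1][:, None]
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return paths, post[..., STATE_AZ]


def decode_autozygosity(
    genotypes: np.ndarray,
    positions: np.ndarray,
    alt_freq: np.ndarray,
    params: HmmParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-individual decode along one chromosome.

    Returns (path, posterior_az) over the input sites; if no informative
    (non-missing) site exists, both are empty arrays.
    """
    params = params or HmmParams()
    g = np.asarray(genotypes, dtype=np.int8)
    if not (g != MISSING).any():
        return np.empty(0, dtype=np.int8), np.empty(0)
    paths, post = decode_chromosome(
        g[:, None], np.asarray(positions), np.asarray(alt_freq, dtype=float), params
    )
    return paths[:, 0], post[:, 0]


@dataclass(frozen=True)
class ROHSegment:
    """Maximal run of AZ-state sites; 1-based inclusive coordinates spanning
    the first to the last site of the run."""

    individual: str
    chrom: str
    start: int
    end: int
    n_sites: int
    mean_posterior: float

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def extract_segments(
    path: np.ndarray,
    positions: np.ndarray,
    posterior_az: np.ndarray | None = None,
    chrom: str = "1",
    individual: str = "ind",
) -> list[ROHSegment]:
    """Turn maximal AZ runs of a decoded state path into segments."""
    path = np.asarray(path)
    if path.size == 0:
        return []
    az = path == STATE_AZ
    edges = np.diff(az.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if az[0]:
        starts = [0] + starts
    if az[-1]:
        ends = ends + [len(az) - 1]
    segs = []
    for s, e in zip(starts, ends):
        mp = float(np.mean(posterior_az[s : e + 1])) if posterior_az is not None else np.nan
        segs.append(
            ROHSegment(
                individual=individual,
                chrom=str(chrom),
                start=int(positions[s]),
                end=int(positions[e]),
                n_sites=int(e - s + 1),
                mean_posterior=mp,
            )
        )
    return segs


def call_roh(ds: GenotypeDataset, params: HmmParams | None = None) -> pd.DataFrame:
    """Decode every individual on every chromosome; return a segment table.

    Columns: individual, chrom, start, end, length_bp, n_sites,
    mean_posterior.  Allele frequencies come from the dataset (cohort
    estimates) unless already overridden in ``ds.sites['alt_freq']``.
    """
    params = params or HmmParams()
    rows = []
    for chrom, idx in ds.sites.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = ds.sites.loc[idx, "pos"].to_numpy()
        freq = ds.sites.loc[idx, "alt_freq"].to_numpy(dtype=float)
        freq = np.clip(np.nan_to_num(freq, nan=0.0), 1e-6, 1 - 1e-6)
        G = ds.genotypes[idx]
        paths, post = decode_chromosome(G, pos, freq, params)
        for k, ind in enumerate(ds.individuals):
            for seg in extract_segments(paths[:, k], pos, post[:, k], chrom, ind):
                rows.append(
                    {
                        "individual": seg.individual,
                        "chrom": seg.chrom,
                        "start": seg.start,
                        "end": seg.end,
                        "length_bp": seg.length_bp,
                        "n_sites": seg.n_sites,
                        "mean_posterior": seg.mean_posterior,
                    }
                )
    cols = ["individual", "chrom", "start", "end", "length_bp", "n_sites", "mean_posterior"]
    return pd.DataFrame(rows, columns=cols)


def compute_froh(
    segments: pd.DataFrame,
    individuals: list[str] | None = None,
    min_len: float = DEFAULT_MIN_LEN,
    bins=DEFAULT_BINS,
    l_auto: float = DEFAULT_L_AUTO,
) -> pd.DataFrame:
    """Per-individual F_ROH = sum(segment lengths >= min_len) / l_auto, binned.

    The first bin is closed on both ends ([min_len, hi]); later bins are
    (lo, hi], so every retained segment falls in exactly one bin and the
    bin values sum to the total exactly.
    """
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    if individuals is None:
        individuals = list(pd.unique(segments["individual"]))
    out = pd.DataFrame(
        0.0, index=pd.Index(individuals, name="individual"),
        columns=["froh_total", *BIN_LABELS[: len(bins)]],
    )
    keep = segments[segments["length_bp"] >= min_len]
    for ind, grp in keep.groupby("individual"):
        if ind not in out.index:
            continue
        lens = grp["length_bp"].to_numpy(dtype=float)
        for (lo, hi), label in zip(bins, BIN_LABELS):
            if lo <= min_len:
                m = (lens >= min_len) & (lens <= hi)
            else:
                m = (lens > lo) & (lens <= hi)
            out.loc[ind, label] = lens[m].sum() / l_auto
        # total as the sum of the bins keeps the partition identity exact
        out.loc[ind, "froh_total"] = out.loc[ind, list(BIN_LABELS[: len(bins)])].sum()
    return out.reset_index()
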