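"""Synthetic genomes, populations, and RNA pileups with planted effects.

The generator emulates the study design the pipeline targets: an inbred-line
genotype panel plus pooled DNA-seq populations of *Drosophila*-like flies, an
outgroup species table for polarization, and multi-sample RNA pileups over
annotated A-to-I editing sites. Effect sizes are planted as parameters — an
excess polymorphism rate at edited A sites, a G-dominated alternative-allele
composition, a mean derived-G frequency shift, a local diversity reduction
around polymorphic edited sites, and per-site editing levels — so every
downstream statistic can be checked against a truth table.

Defaults follow the observed study conditions: edited sites are polymorphic
at ~21% against ~2% genome-wide, G is the alternative allele at ~98% of
edited polymorphisms (~45/20/35 G/C/T at unedited ones), the derived-G
frequency at edited sites is shifted up by 0.12 on average, and the mean
editing level is 0.23.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    Genome,
    write_edit_bed,
    write_gff3,
    write_outgroup_tsv,
    write_pileups,
    write_pool_tsv,
    write_recomb_map,
    write_vcf,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults are the planted study conditions."""

    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.42
    n_genes: int = 120
    n_edit_sites: int = 3581
    n_lines: int = 100
    pool_mean_coverage: float = 60.0
    p_poly_unedited: float = 0.02
    p_poly_edited: float = 0.21
    # simplexes over the sense alternative alleles (G, C, T) relative to A
    alt_allele_probs_edited: tuple[float, float, float] = (0.980, 0.004, 0.016)
    alt_allele_probs_unedited: tuple[float, float, float] = (0.448, 0.195, 0.357)
    derived_freq_shift: float = 0.12
    sweep_diversity_factor: float = 0.85
    sweep_radius: int = 5_000
    mean_editing_level: float = 0.23
    outgroup_divergence: float = 0.05
    seed: int = 0
    # secondary knobs, documented in the methods note
    edit_genic_fraction: float = 0.3
    error_rate: float = 0.001
    rna_depth: float = 100.0

    def validate(self) -> None:
        for name in (
            "gc_fraction", "p_poly_unedited", "p_poly_edited",
            "mean_editing_level", "outgroup_divergence", "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("alt_allele_probs_edited", "alt_allele_probs_unedited"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{name} is not a simplex: {probs}")
        if not 0.0 < self.sweep_diversity_factor <= 1.0:
            raise ValueError("sweep_diversity_factor must be in (0, 1]")
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if min(self.genome_length, self.n_chromosomes) < 1:
            raise ValueError("genome_length and n_chromosomes must be positive")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


@dataclass
class ReferenceBundle:
    genome: Genome
    genes: pd.DataFrame      # gene_id, chrom, start, end, strand (CDS == span)
    edits: pd.DataFrame      # chrom, pos, strand
    recomb: pd.DataFrame     # chrom, pos, cM
    params: SimulationParams


@dataclass
class PopulationBundle:
    snps: pd.DataFrame       # chrom,pos,ref,alt,strand,sense_alt,is_edited,count,freq
    genotypes: np.ndarray    # (n_snps, n_lines) uint8, 1 = homozygous derived
    line_names: list[str]
    pool: pd.DataFrame       # snps + g, r
    outgroup: pd.DataFrame   # chrom, pos, outgroup_alleles (covered sites)
    divergence: pd.DataFrame  # chrom, pos (fixed interspecies differences)
    truth: pd.DataFrame
    # sweep thinning removes unedited SNPs after the polymorphism draw, so the
    # marginal unedited rate in the emitted data is below p_poly_unedited;
    # recovery against the planted rate must add this count back.
    n_thinned_unedited: int = 0


# ---------------------------------------------------------------------------
# neutral spectrum and its reweighting

def neutral_spectrum(n_lines: int) -> np.ndarray:
    """P(derived count = i) ∝ 1/i over i = 1..n−1 (standard neutral SFS)."""
    i = np.arange(1, n_lines)
    p = 1.0 / i
    return p / p.sum()


def shifted_spectrum(n_lines: int, shift: float) -> np.ndarray:
    """Exponentially tilt the neutral spectrum so its mean frequency rises by
    ``shift``. Raises if the target mean is infeasible on the support."""
    i = np.arange(1, n_lines)
    base = neutral_spectrum(n_lines)
    target = base @ i + shift * n_lines
    if not i[0] < target < i[-1]:
        raise ValueError(
            f"derived_freq_shift={shift} infeasible: target mean count {target:.2f} "
            f"outside support (1, {n_lines - 1})"
        )

    def mean_at(lam: float) -> float:
        logw = np.log(base) + lam * i
        w = np.exp(logw - logw.max())
        w /= w.sum()
        return float(w @ i) - target

    lo, hi = -1.0, 1.0
    while mean_at(lo) > 0:
        lo *= 2
    while mean_at(hi) < 0:
        hi *= 2
    lam = brentq(mean_at, lo, hi, xtol=1e-12)
    logw = np.log(base) + lam * i
    w = np.exp(logw - logw.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# reference bundle

def generate_reference(params: SimulationParams) -> ReferenceBundle:
    params.validate()
    rng = np.random.default_rng(params.seed)
    gc = params.gc_fraction
    base_p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    chrom_len = params.genome_length // params.n_chromosomes
    seqs: dict[str, str] = {}
    for c in range(params.n_chromosomes):
        idx = rng.choice(4, size=chrom_len, p=base_p)
        seqs[f"chr{c + 1}"] = _BASES[idx].tobytes().decode()
    genome = Genome(seqs)

    genes = _place_genes(params, rng, chrom_len)
    edits = _place_edits(params, rng, genome, genes)
    recomb = _make_recomb_map(params, rng, genome)
    return ReferenceBundle(genome, genes, edits, recomb, params)


def _place_genes(params, rng, chrom_len) -> pd.DataFrame:
    rows = []
    per_chrom = params.n_genes // params.n_chromosomes
    extra = params.n_genes - per_chrom * params.n_chromosomes
    gid = 0
    for c in range(params.n_chromosomes):
        n_here = per_chrom + (1 if c < extra else 0)
        if n_here == 0:
            continue
        slot = chrom_len // n_here
        for k in range(n_here):
            max_len = max(300, min(1500, int(slot * 0.6)))
            length = 3 * int(rng.integers(100, max(101, max_len // 3)))
            start = slot * k + int(rng.integers(0, max(1, slot - length)))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gid:04d}", f"chr{c + 1}", start, start + length, strand))
            gid += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _sense_a_positions(genome: Genome, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions of genomic A (sense +) and T (sense −) on one chromosome."""
    arr = genome.char_array(chrom)
    return np.flatnonzero(arr == b"A"), np.flatnonzero(arr == b"T")


def _place_edits(params, rng, genome: Genome, genes: pd.DataFrame) -> pd.DataFrame:
    """Sample editing sites on reference A (+) / T (−), a genic fraction inside CDS."""
    genic_target = int(round(params.edit_genic_fraction * params.n_edit_sites))
    rows = []
    cand_genic: list[tuple[str, int, str]] = []
    cand_other: list[tuple[str, int, str]] = []
    for chrom in genome.chroms:
        a_pos, t_pos = _sense_a_positions(genome, chrom)
        gsub = genes[genes["chrom"] == chrom]
        # editing happens on the transcribed strand: inside a CDS only the
        # coding-sense adenosine (genomic A in + genes, T in − genes) is a
        # genic candidate
        in_plus = np.zeros(genome.lengths[chrom], dtype=bool)
        in_minus = np.zeros(genome.lengths[chrom], dtype=bool)
        for g in gsub.itertuples(index=False):
            (in_plus if g.strand == "+" else in_minus)[g.start : g.end] = True
        in_cds = in_plus | in_minus
        for pos_arr, strand, sense_cds in ((a_pos, "+", in_plus), (t_pos, "-", in_minus)):
            genic = sense_cds[pos_arr]
            other = ~in_cds[pos_arr]
            cand_genic.extend((chrom, int(p), strand) for p in pos_arr[genic])
            cand_other.extend((chrom, int(p), strand) for p in pos_arr[other])
    n_other = params.n_edit_sites - genic_target
    if genic_target > len(cand_genic) or n_other > len(cand_other):
        raise ValueError(
            f"n_edit_sites={params.n_edit_sites} exceeds available A/T positions "
            f"(genic {len(cand_genic)} < {genic_target} or "
            f"other {len(cand_other)} < {n_other})"
        )
    for cands, n in ((cand_genic, genic_target), (cand_other, n_other)):
        if n:
            take = rng.choice(len(cands), size=n, replace=False)
            rows.extend(cands[i] for i in take)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _make_recomb_map(params, rng, genome: Genome) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.lengths.items():
        anchors = list(range(0, length, 200_000)) + [length - 1]
        cm = np.concatenate([[0.0], np.cumsum(rng.gamma(2.0, 0.2, len(anchors) - 1))])
        rows.extend((chrom, p, c) for p, c in zip(anchors, cm))
    return pd.DataFrame(rows, columns=["chrom", "pos", "cM"])


# ---------------------------------------------------------------------------
# population bundle

def generate_population(ref: ReferenceBundle, params: SimulationParams | None = None
                        ) -> PopulationBundle:
    params = params or ref.params
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n = params.n_lines

    edited_keys = set(zip(ref.edits["chrom"], ref.edits["pos"]))
    site_rows = []
    for chrom in ref.genome.chroms:
        a_pos, t_pos = _sense_a_positions(ref.genome, chrom)
        for pos_arr, strand in ((a_pos, "+"), (t_pos, "-")):
            edited = np.fromiter(
                ((chrom, int(p)) in edited_keys for p in pos_arr),
                dtype=bool, count=len(pos_arr),
            )
            site_rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos_arr, "strand": strand, "is_edited": edited}
                )
            )
    sites = pd.concat(site_rows, ignore_index=True)

    p_poly = np.where(sites["is_edited"], params.p_poly_edited, params.p_poly_unedited)
    poly = sites[rng.random(len(sites)) < p_poly].reset_index(drop=True)

    # sense alternative allele from the class simplex
    alt_idx = np.empty(len(poly), dtype=int)
    for flag, probs in (
        (True, params.alt_allele_probs_edited),
        (False, params.alt_allele_probs_unedited),
    ):
        mask = poly["is_edited"].to_numpy() == flag
        alt_idx[mask] = rng.choice(3, size=int(mask.sum()), p=probs)
    sense_alt = np.array(["G", "C", "T"])[alt_idx]
    poly["sense_alt"] = sense_alt
    minus = (poly["strand"] == "-").to_numpy()
    poly["ref"] = np.where(minus, "T", "A")
    poly["alt"] = np.where(minus, [_COMP[b] for b in sense_alt], sense_alt)

    # derived counts: neutral 1/i law, exponentially tilted at edited sites
    counts = np.empty(len(poly), dtype=int)
    base = neutral_spectrum(n)
    tilted = shifted_spectrum(n, params.derived_freq_shift)
    support = np.arange(1, n)
    em = poly["is_edited"].to_numpy()
    counts[~em] = rng.choice(support, size=int((~em).sum()), p=base)
    counts[em] = rng.choice(support, size=int(em.sum()), p=tilted)
    poly["count"] = counts
    poly["freq"] = counts / n

    n_before = len(poly)
    poly = _thin_sweep_flanks(poly, params, rng)
    n_thinned = n_before - len(poly)
    poly = poly.sort_values(["chrom", "pos"]).reset_index(drop=True)

    # panel genotypes: `count` lines homozygous derived per SNP
    keys = rng.random((len(poly), n))
    order = np.argsort(keys, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n)[None, :].repeat(len(poly), 0), axis=1)
    genotypes = (ranks < poly["count"].to_numpy()[:, None]).astype(np.uint8)
    line_names = [f"line{j + 1:03d}" for j in range(n)]

    # pooled DNA-seq counts
    r = rng.poisson(params.pool_mean_coverage, len(poly))
    g = rng.binomial(r, poly["freq"].to_numpy())
    pool = poly.copy()
    pool["g"], pool["r"] = g, r

    outgroup, divergence = _make_outgroup(ref, poly, params, rng)
    truth = _make_truth(ref, poly, params, rng)
    return PopulationBundle(
        poly, genotypes, line_names, pool, outgroup, divergence, truth, n_thinned
    )


def _thin_sweep_flanks(poly: pd.DataFrame, params, rng) -> pd.DataFrame:
    """Drop unedited polymorphisms near polymorphic edited sites with
    probability 1 − sweep_diversity_factor (the planted sweep footprint)."""
    if params.sweep_diversity_factor >= 1.0:
        return poly
    keep = np.ones(len(poly), dtype=bool)
    for chrom, grp in poly.groupby("chrom", sort=False):
        centers = grp.loc[grp["is_edited"], "pos"].to_numpy()
        if len(centers) == 0:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(centers, pos - params.sweep_radius, side="left")
        hi = np.searchsorted(centers, pos + params.sweep_radius, side="right")
        near = (hi > lo) & ~grp["is_edited"].to_numpy()
        drop = near & (rng.random(len(grp)) < 1.0 - params.sweep_diversity_factor)
        keep[grp.index[drop]] = False
    return poly[keep].reset_index(drop=True)


def _make_outgroup(ref, poly, params, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outgroup = ancestral (reference) allele at all polymorphic sites, plus
    divergent substitutions at a fraction of monomorphic positions."""
    rows = [
        pd.DataFrame(
            {
                "chrom": poly["chrom"],
                "pos": poly["pos"],
                "outgroup_alleles": poly["ref"],
            }
        )
    ]
    poly_keys = set(zip(poly["chrom"], poly["pos"]))
    div_rows = []
    for chrom, length in ref.genome.lengths.items():
        hits = np.flatnonzero(rng.random(length) < params.outgroup_divergence)
        arr = ref.genome.char_array(chrom)
        for p in hits:
            if (chrom, int(p)) in poly_keys:
                continue
            refb = arr[p].decode()
            choices = [b for b in "ACGT" if b != refb]
            div_rows.append((chrom, int(p), choices[int(rng.integers(3))]))
    div = pd.DataFrame(div_rows, columns=["chrom", "pos", "outgroup_alleles"])
    out = pd.concat(rows + [div], ignore_index=True)
    out = out.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out, div[["chrom", "pos"]].reset_index(drop=True)


def _make_truth(ref, poly, params, rng) -> pd.DataFrame:
    poly_keys = {(c, p): i for i, (c, p) in enumerate(zip(poly["chrom"], poly["pos"]))}
    rows = []
    mean = params.mean_editing_level
    a = 10.0 * mean
    b = 10.0 * (1 - mean)
    for e in ref.edits.itertuples(index=False):
        idx = poly_keys.get((e.chrom, e.pos))
        level = float(rng.beta(a, b)) if mean > 0 else 0.0
        if idx is None:
            rows.append(
                (e.chrom, e.pos, e.strand, True, False, "A", "", 0.0, level, False)
            )
        else:
            row = poly.iloc[idx]
            rows.append(
                (
                    e.chrom, e.pos, e.strand, True, True, "A", row["sense_alt"],
                    float(row["freq"]), level, True,
                )
            )
    for row in poly[~poly["is_edited"]].itertuples(index=False):
        rows.append(
            (
                row.chrom, row.pos, row.strand, False, True, "A", row.sense_alt,
                float(row.freq), 0.0, False,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "is_edited", "is_polymorphic",
            "ancestral", "derived", "derived_freq", "editing_level", "in_sweep_region",
        ],
    )
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# RNA pileups

def generate_rna_pileups(
    ref: ReferenceBundle,
    truth: pd.DataFrame,
    n_samples: int,
    params: SimulationParams | None = None,
    n_control_sites: int | None = None,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Per-sample base counts at edited sites plus unedited control A/T sites.

    At an edited site the edited-read count is Binomial(depth, level) on the
    annotated strand (G reads on +, C reads on −); at unedited sites such
    reads arise only at the sequencing error rate. With ``deterministic``
    the sampling noise is removed: depth is exactly ``rna_depth`` and the
    edited-read count is round(depth × level) — the noise-free regime in
    which the caller is provably exact.
    """
    params = params or ref.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    edited = truth[truth["is_edited"]]
    n_control = n_control_sites if n_control_sites is not None else len(edited)

    edited_keys = set(zip(edited["chrom"], edited["pos"]))
    controls: list[tuple[str, int, str, float]] = []
    for chrom in ref.genome.chroms:
        a_pos, t_pos = _sense_a_positions(ref.genome, chrom)
        for pos_arr, strand in ((a_pos, "+"), (t_pos, "-")):
            controls.extend(
                (chrom, int(p), strand, 0.0)
                for p in pos_arr
                if (chrom, int(p)) not in edited_keys
            )
    take = rng.choice(len(controls), size=min(n_control, len(controls)), replace=False)
    site_list = [
        (r.chrom, r.pos, r.strand, r.editing_level)
        for r in edited.itertuples(index=False)
    ] + [controls[i] for i in sorted(take)]

    rows = []
    for chrom, pos, strand, level in site_list:
        for s in range(n_samples):
            p_edit = level if level > 0 else params.error_rate
            if deterministic:
                depth = int(round(params.rna_depth))
                n_edit = int(round(depth * p_edit))
            else:
                depth = int(rng.poisson(params.rna_depth))
                n_edit = int(rng.binomial(depth, p_edit)) if depth else 0
            counts = {"A": 0, "C": 0, "G": 0, "T": 0}
            if strand == "+":
                counts["G"] = n_edit
                counts["A"] = depth - n_edit
            else:
                counts["C"] = n_edit
                counts["T"] = depth - n_edit
            rows.append(
                (chrom, pos, f"s{s + 1:02d}", counts["A"], counts["C"], counts["G"], counts["T"])
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "sample", "nA", "nC", "nG", "nT"])
    return df.sort_values(["chrom", "pos", "sample"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# planted haplotype structure for the EHH/iHS scan

def simulate_haplotypes(
    n_hap: int,
    n_markers: int,
    core_freq: float,
    sweep: bool,
    rng: np.random.Generator,
    n_founders: int = 8,
    switch_prob: float = 0.08,
    marker_spacing: float = 1_000.0,
    cm_per_mb: float = 2.0,
    sweep_mut_prob: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block-mosaic haplotypes with an optional planted sweep at the core.

    Haplotypes are mosaics of ``n_founders`` founder patterns with geometric
    block switching (a stand-in for recombination). Under ``sweep`` the
    derived-core carriers are near-copies of one founder, giving them a long
    shared flank; otherwise carriers are a random subset. Returns the 0/1
    matrix, physical marker positions (bp) and map positions (cM).
    """
    founders = rng.integers(0, 2, size=(n_founders, n_markers), dtype=np.uint8)
    fid = np.empty((n_hap, n_markers), dtype=int)
    fid[:, 0] = rng.integers(0, n_founders, n_hap)
    for m in range(1, n_markers):
        switch = rng.random(n_hap) < switch_prob
        fid[:, m] = np.where(switch, rng.integers(0, n_founders, n_hap), fid[:, m - 1])
    hap = founders[fid, np.arange(n_markers)[None, :]]

    core = n_markers // 2
    n_der = max(2, int(round(core_freq * n_hap)))
    n_der = min(n_der, n_hap - 2)
    if sweep:
        template = founders[0]
        carriers = rng.choice(n_hap, size=n_der, replace=False)
        for h in carriers:
            noise = rng.random(n_markers) < sweep_mut_prob
            hap[h] = np.where(noise, 1 - template, template)
    else:
        carriers = rng.choice(n_hap, size=n_der, replace=False)
    hap[:, core] = 0
    hap[carriers, core] = 1

    positions = np.arange(n_markers) * marker_spacing
    map_cm = positions * cm_per_mb / 1e6
    return hap.astype(np.uint8), positions, map_cm


# ---------------------------------------------------------------------------
# bundle writer

def write_bundle(ref: ReferenceBundle, pop: PopulationBundle, outdir,
                 pileups: pd.DataFrame | None = None) -> dict[str, str]:
    """Emit the full file bundle in the external dialects; deterministic bytes."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    ref.genome.to_fasta(outdir / "genome.fa")
    paths["genome"] = str(outdir / "genome.fa")
    write_gff3(ref.genes, outdir / "genes.gff3")
    paths["genes"] = str(outdir / "genes.gff3")
    write_edit_bed(ref.edits, outdir / "edits.bed")
    paths["edits"] = str(outdir / "edits.bed")
    write_recomb_map(ref.recomb, outdir / "recomb_map.tsv")
    paths["recomb"] = str(outdir / "recomb_map.tsv")

    write_vcf(
        pop.snps, pop.genotypes, pop.line_names, ref.genome.lengths,
        outdir / "variants.vcf",
    )
    paths["variants"] = str(outdir / "variants.vcf")
    write_pool_tsv(pop.pool, outdir / "pool_counts.tsv")
    paths["pool"] = str(outdir / "pool_counts.tsv")
    write_outgroup_tsv(pop.outgroup, outdir / "outgroup_sites.tsv")
    paths["outgroup"] = str(outdir / "outgroup_sites.tsv")

    truth = pop.truth.copy()
    truth["pos1"] = truth["pos"] + 1
    cols = ["chrom", "pos1", "strand", "is_edited", "is_polymorphic",
            "ancestral", "derived", "derived_freq", "editing_level", "in_sweep_region"]
    truth[cols].to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.6f")
    paths["truth"] = str(outdir / "truth.tsv")

    if pileups is not None:
        write_pileups(pileups, outdir / "pileups.tsv")
        paths["pileups"] = str(outdir / "pileups.tsv")
    return paths
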