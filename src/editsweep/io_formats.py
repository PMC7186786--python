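"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open. Dialect conversions happen
exactly once, at the file boundary: BED passes through, GFF3/VCF/AXT and the
1-based TSV dialects are shifted on read and restored on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class Genome:
    """In-memory random-access genome. Bases are upper-cased on load."""

    def __init__(self, seqs: dict[str, str]):
        if not seqs:
            raise ValueError("genome has no sequences")
        self._seqs = {name: s.upper() for name, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence name {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError(f"no FASTA records in {path}")
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in self._seqs:
                fh.write(f">{name}\n")
                s = self._seqs[name]
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self._seqs[chrom][pos]

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def char_array(self, chrom: str) -> np.ndarray:
        """Chromosome as an ``S1`` numpy array for vectorised base scans."""
        return np.frombuffer(self._seqs[chrom].encode(), dtype="S1")


# ---------------------------------------------------------------------------
# intervals

_GFF_COLS = [
    "chrom", "source", "feature", "start", "end",
    "score", "strand", "frame", "attributes",
]


def load_intervals(path: str | Path, dialect: str) -> pd.DataFrame:
    """Load BED or GFF3 intervals into 0-based half-open coordinates.

    Returns a frame with at least chrom/start/end/strand; GFF3 keeps the
    feature type and attribute column, BED keeps any extra columns.
    """
    if dialect == "BED":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str}
        )
        ncol = df.shape[1]
        names = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
        names += [f"extra{i}" for i in range(ncol - len(names))]
        df.columns = names
        if "strand" in df.columns:
            bad = ~df["strand"].isin(["+", "-"])
            if bad.any():
                raise ValueError(
                    f"unknown strand symbol {df.loc[bad, 'strand'].iloc[0]!r} in {path}"
                )
        else:
            df["strand"] = "+"
    elif dialect == "GFF3":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", names=_GFF_COLS,
            dtype={"chrom": str},
        )
        df["start"] = df["start"].astype(int) - 1
        bad = ~df["strand"].isin(["+", "-", "."])
        if bad.any():
            raise ValueError(
                f"unknown strand symbol {df.loc[bad, 'strand'].iloc[0]!r} in {path}"
            )
    else:
        raise ValueError(f"unknown interval dialect {dialect!r}")
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        row = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(
            f"empty/inverted interval {row['chrom']}:{row['start']}-{row['end']} in {path}"
        )
    return df


def load_edit_sites(path: str | Path) -> pd.DataFrame:
    """Load an editing-site BED (strand column required, + = edited A, − = edited T)."""
    df = load_intervals(path, "BED")
    if "strand" not in df.columns or df.shape[1] < 6:
        raise ValueError(f"editing-site BED {path} must carry a strand column")
    out = pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["start"], "strand": df["strand"]}
    )
    for src, dst in (("extra0", "level"), ("extra1", "n_samples")):
        if src in df.columns:
            out[dst] = df[src]
    return out


def write_edit_bed(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            extras = ""
            if hasattr(row, "level"):
                extras += f"\t{row.level:.6g}"
            if hasattr(row, "n_samples"):
                extras += f"\t{int(row.n_samples)}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\tedit\t0\t{row.strand}{extras}\n"
            )


# ---------------------------------------------------------------------------
# variants

POOL_COLUMNS = ["chrom", "pos1", "ref", "alt", "alt_reads", "total_reads"]


@dataclass
class VariantSet:
    """Biallelic SNVs in one of two modes: inbred-panel genotypes or pool counts."""

    snps: pd.DataFrame
    mode: str  # "panel" | "pool"
    n_skipped_multiallelic: int = 0
    samples: list[str] = field(default_factory=list)


def load_variants(
    path: str | Path, dialect: str, genome: Genome | None = None
) -> VariantSet:
    if dialect == "VCF":
        return _load_vcf(path, genome)
    if dialect == "pool_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(POOL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"pool TSV {path} missing columns {sorted(missing)}")
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": df["pos1"].astype(int) - 1,
                "ref": df["ref"],
                "alt": df["alt"],
                "g": df["alt_reads"].astype(int),
                "r": df["total_reads"].astype(int),
            }
        )
        if ((out["g"] < 0) | (out["g"] > out["r"])).any():
            raise ValueError("pool counts must satisfy 0 <= alt_reads <= total_reads")
        _check_ref(out, genome, path)
        return VariantSet(out, "pool")
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _load_vcf(path: str | Path, genome: Genome | None) -> VariantSet:
    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            gt_ref = gt_alt = n_het = n_missing = 0
            for s in rec.samples.values():
                gt = s.get("GT")
                if gt is None or None in gt:
                    n_missing += 1
                elif all(a == 0 for a in gt):
                    gt_ref += 1
                elif all(a == 1 for a in gt):
                    gt_alt += 1
                else:
                    n_het += 1
            rows.append(
                (rec.chrom, rec.pos - 1, rec.ref, alts[0], gt_ref, gt_alt, n_het, n_missing)
            )
    if skipped:
        logger.info("load_variants: skipped %d multiallelic/non-SNV records", skipped)
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "gt_ref", "gt_alt", "n_het", "n_missing"],
    )
    _check_ref(df, genome, path)
    return VariantSet(df, "panel", skipped, samples)


def _check_ref(df: pd.DataFrame, genome: Genome | None, path) -> None:
    if genome is None or df.empty:
        return
    for chrom, grp in df.groupby("chrom", sort=False):
        arr = genome.char_array(chrom)
        got = arr[grp["pos"].to_numpy()].astype("U1")
        bad = got != grp["ref"].to_numpy()
        if bad.any():
            pos = grp["pos"].to_numpy()[bad][0]
            raise ValueError(
                f"{path}: REF mismatch with genome at {chrom}:{pos + 1}"
            )


def write_vcf(
    snps: pd.DataFrame,
    genotypes: np.ndarray,
    samples: list[str],
    contigs: dict[str, int],
    path: str | Path,
) -> None:
    """Write a minimal deterministic VCFv4.2 with homozygous GT per inbred line.

    ``genotypes`` is an (n_snps, n_lines) 0/1 array; 1 means homozygous ALT.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=editsweep\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i, row in enumerate(snps.itertuples(index=False)):
            gts = "\t".join("1/1" if g else "0/0" for g in genotypes[i])
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_pool_tsv(snps: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "pos1": snps["pos"] + 1,
            "ref": snps["ref"],
            "alt": snps["alt"],
            "alt_reads": snps["g"],
            "total_reads": snps["r"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# outgroup

class Outgroup:
    """Per-site outgroup allele sets keyed by (chrom, 0-based pos)."""

    def __init__(self, alleles: dict[tuple[str, int], frozenset[str]],
                 n_conflicts: int = 0):
        self._alleles = alleles
        self.n_conflicts = n_conflicts

    def get(self, chrom: str, pos: int) -> frozenset[str] | None:
        return self._alleles.get((chrom, pos))

    def __len__(self) -> int:
        return len(self._alleles)

    def items(self):
        return self._alleles.items()


def load_outgroup(path: str | Path, dialect: str) -> Outgroup:
    if dialect == "AXT":
        return _load_axt(path)
    if dialect == "site_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        alleles = {
            (row.chrom, int(row.pos1) - 1): frozenset(
                str(row.outgroup_alleles).replace(",", "")
            )
            for row in df.itertuples(index=False)
        }
        return Outgroup(alleles)
    raise ValueError(f"unknown outgroup dialect {dialect!r}")


def _load_axt(path: str | Path) -> Outgroup:
    """Parse UCSC AXT pairwise alignments, reference-anchored.

    Block layout: a summary line (index, ref chrom, 1-based ref start/end,
    query chrom/coords, query strand, score) followed by the two gapped
    sequences. Gap columns in the reference consume no reference coordinate;
    gap or N columns in the query leave the site uncovered.
    """
    alleles: dict[tuple[str, int], frozenset[str]] = {}
    conflicts = 0
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    for i in range(0, len(lines), 3):
        header = lines[i].split()
        chrom, start1 = header[1], int(header[2])
        ref_seq, query_seq = lines[i + 1].upper(), lines[i + 2].upper()
        pos = start1 - 1
        for rbase, qbase in zip(ref_seq, query_seq):
            if rbase == "-":
                continue
            if qbase not in "-N":
                key = (chrom, pos)
                if key in alleles:
                    conflicts += 1  # overlapping blocks: keep first
                else:
                    alleles[key] = frozenset(qbase)
            pos += 1
    if conflicts:
        logger.info("load_outgroup: %d overlapping AXT columns ignored", conflicts)
    return Outgroup(alleles, conflicts)


def write_outgroup_tsv(out: Outgroup | pd.DataFrame, path: str | Path) -> None:
    if isinstance(out, pd.DataFrame):
        df = out.copy()
        df["pos1"] = df["pos"] + 1
        df = df[["chrom", "pos1", "outgroup_alleles"]]
    else:
        rows = sorted(
            ((c, p + 1, "".join(sorted(a))) for (c, p), a in out.items())
        )
        df = pd.DataFrame(rows, columns=["chrom", "pos1", "outgroup_alleles"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simple TSV tables

def load_recomb_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["pos1"].astype(int) - 1, "cM": df["cM"].astype(float)}
    )
    for _, grp in df.groupby("chrom"):
        if not (np.diff(grp["cM"].to_numpy()) >= 0).all() or not (
            np.diff(grp["pos"].to_numpy()) > 0
        ).all():
            raise ValueError(f"recombination map {path} not monotone")
    return df


def write_recomb_map(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"chrom": df["chrom"], "pos1": df["pos"] + 1, "cM": df["cM"]})
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_pileups(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    df["pos"] = df["pos1"].astype(int) - 1
    return df[["chrom", "pos", "sample", "nA", "nC", "nG", "nT"]]


def write_pileups(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos1": df["pos"] + 1,
            "sample": df["sample"],
            "nA": df["nA"],
            "nC": df["nC"],
            "nG": df["nG"],
            "nT": df["nT"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def load_known_snps(path: str | Path) -> dict[tuple[str, int], float]:
    """Known-SNP exclusion list (chrom, pos1, alt, freq) → max freq per site."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[tuple[str, int], float] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos1) - 1)
        out[key] = max(out.get(key, 0.0), float(row.freq))
    return out


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write single-CDS gene models (gene + mRNA + CDS rows per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            s, e = row.start + 1, row.end  # GFF3 is 1-based closed
            gid = row.gene_id
            fh.write(
                f"{row.chrom}\teditsweep\tgene\t{s}\t{e}\t.\t{row.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{row.chrom}\teditsweep\tmRNA\t{s}\t{e}\t.\t{row.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            fh.write(
                f"{row.chrom}\teditsweep\tCDS\t{s}\t{e}\t.\t{row.strand}\t0\t"
                f"ID={gid}.cds;Parent={gid}.t1\n"
            )


def translate(seq: str) -> str:
    return str(Seq(seq).translate())
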