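"""Coding consequences of hypothetical A→G replacements and the f_s/f_n rates.

Every adenosine in coding sequence (genomic A in a + strand CDS, genomic T
in a − strand CDS) is classified by translating its codon before and after
an A→G substitution under the standard nuclear code. The rate table then
relates observed A,G polymorphism counts to these potential-site counts:
f = polymorphic / potential, separately for synonymous and nonsynonymous
sites and for edited vs genome-wide A sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Genome, revcomp, translate

logger = logging.getLogger(__name__)

_EFFECT_PRIORITY = ["stop_gain", "stop_loss", "nonsynonymous", "synonymous"]


def _effect_of_a_to_g(codon: str, codon_pos: int) -> str:
    aa_ref = translate(codon)
    mutated = codon[:codon_pos] + "G" + codon[codon_pos + 1:]
    aa_alt = translate(mutated)
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gain"
    if aa_ref == "*":
        return "stop_loss"
    return "nonsynonymous"


def _cds_parts(gff: pd.DataFrame) -> pd.DataFrame:
    """CDS rows grouped into transcripts. Accepts either a GFF3 frame (with
    feature/attributes columns) or a simple gene table (gene_id span rows)."""
    if "feature" in gff.columns:
        cds = gff[gff["feature"] == "CDS"].copy()
        cds["transcript"] = (
            cds["attributes"].str.extract(r"Parent=([^;]+)", expand=False)
            .fillna(cds["attributes"].str.extract(r"ID=([^;]+)", expand=False))
        )
        return cds[["transcript", "chrom", "start", "end", "strand"]]
    out = gff.rename(columns={"gene_id": "transcript"})
    return out[["transcript", "chrom", "start", "end", "strand"]]


def classify_A_sites(genome: Genome, gene_models: pd.DataFrame) -> pd.DataFrame:
    """Per-site coding effect of A→G for every coding-sense A inside CDS.

    Returns chrom, pos (genomic), strand (coding), gene/transcript id, codon,
    codon_pos and effect. A sites outside any CDS are implicitly noncoding.
    Transcripts whose CDS length is not divisible by 3 are skipped with a
    warning. At positions covered by several transcripts the labels are
    merged conservatively: synonymous only if synonymous in every frame,
    otherwise the most consequential label wins.
    """
    rows = []
    for transcript, parts in _cds_parts(gene_models).groupby("transcript", sort=True):
        parts = parts.sort_values("start")
        chrom = parts["chrom"].iloc[0]
        strand = parts["strand"].iloc[0]
        if chrom not in genome:
            logger.warning("classify_A_sites: %s on unknown chrom %s", transcript, chrom)
            continue
        genomic_pos = np.concatenate(
            [np.arange(p.start, p.end) for p in parts.itertuples(index=False)]
        )
        seq = "".join(
            genome.fetch(chrom, p.start, p.end) for p in parts.itertuples(index=False)
        )
        if len(seq) % 3 != 0:
            logger.warning(
                "classify_A_sites: CDS of %s not divisible by 3, skipped", transcript
            )
            continue
        if strand == "-":
            seq = revcomp(seq)
            genomic_pos = genomic_pos[::-1]
        for i, base in enumerate(seq):
            if base != "A":
                continue
            codon_start = (i // 3) * 3
            codon = seq[codon_start : codon_start + 3]
            codon_pos = i - codon_start
            effect = _effect_of_a_to_g(codon, codon_pos)
            rows.append(
                (chrom, int(genomic_pos[i]), strand, transcript, codon, codon_pos, effect)
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "transcript", "codon", "codon_pos", "effect"],
    )
    if df.empty:
        return df
    return _merge_overlaps(df)


def _merge_overlaps(df: pd.DataFrame) -> pd.DataFrame:
    def merge(grp: pd.DataFrame) -> pd.Series:
        effects = set(grp["effect"])
        if effects == {"synonymous"}:
            eff = "synonymous"
        else:
            eff = next(e for e in _EFFECT_PRIORITY if e in effects)
        first = grp.iloc[0]
        return pd.Series(
            {
                "strand": first["strand"],
                "transcript": ",".join(sorted(set(grp["transcript"]))),
                "codon": first["codon"],
                "codon_pos": first["codon_pos"],
                "effect": eff,
            }
        )

    merged = (
        df.groupby(["chrom", "pos"], sort=True)
        .apply(merge, include_groups=False)
        .reset_index()
    )
    return merged


@dataclass
class RateTable:
    """Potential-site counts and A,G polymorphism rates, genome vs edited."""

    S: int
    N: int
    S_edited: int
    N_edited: int
    poly_s: int
    poly_n: int
    poly_s_edited: int
    poly_n_edited: int

    def _rate(self, k: int, n: int) -> float | None:
        return k / n if n else None

    @property
    def f_s(self):
        return self._rate(self.poly_s, self.S)

    @property
    def f_n(self):
        return self._rate(self.poly_n, self.N)

    @property
    def f_s_edited(self):
        return self._rate(self.poly_s_edited, self.S_edited)

    @property
    def f_n_edited(self):
        return self._rate(self.poly_n_edited, self.N_edited)

    def fold(self, which: str, rounded: bool = True) -> float | None:
        """edited rate / genome rate; ``rounded`` divides 3-decimal rounded
        rates (the printed-table convention), else exact rates."""
        pairs = {"s": (self.f_s_edited, self.f_s), "n": (self.f_n_edited, self.f_n)}
        e, g = pairs[which]
        if e is None or g is None or g == 0:
            return None
        if rounded:
            e, g = round(e, 3), round(g, 3)
            if g == 0:
                return None
        return e / g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": ["synonymous", "nonsynonymous"],
                "potential": [self.S, self.N],
                "potential_edited": [self.S_edited, self.N_edited],
                "polymorphic": [self.poly_s, self.poly_n],
                "polymorphic_edited": [self.poly_s_edited, self.poly_n_edited],
                "rate": [self.f_s, self.f_n],
                "rate_edited": [self.f_s_edited, self.f_n_edited],
                "fold": [self.fold("s"), self.fold("n")],
                "fold_exact": [self.fold("s", rounded=False), self.fold("n", rounded=False)],
            }
        )


def _is_nonsyn(effect: str) -> bool:
    return effect in ("nonsynonymous", "stop_gain", "stop_loss")


def compute_rate_table(
    contexts: pd.DataFrame,
    snps: pd.DataFrame,
    edited_sites: pd.DataFrame,
) -> RateTable:
    """Count potential and observed sense A,G polymorphisms per effect class.

    ``snps`` must be restricted to (sense) A,G polymorphisms; matching is by
    (chrom, pos). ``edited_sites`` needs chrom/pos columns.
    """
    edited_keys = set(zip(edited_sites["chrom"], edited_sites["pos"]))
    snp_keys = set(zip(snps["chrom"], snps["pos"]))

    syn = contexts["effect"] == "synonymous"
    nonsyn = contexts["effect"].map(_is_nonsyn)
    keys = list(zip(contexts["chrom"], contexts["pos"]))
    is_edited = np.fromiter((k in edited_keys for k in keys), bool, len(keys))
    is_poly = np.fromiter((k in snp_keys for k in keys), bool, len(keys))

    return RateTable(
        S=int(syn.sum()),
        N=int(nonsyn.sum()),
        S_edited=int((syn & is_edited).sum()),
        N_edited=int((nonsyn & is_edited).sum()),
        poly_s=int((syn & is_poly).sum()),
        poly_n=int((nonsyn & is_poly).sum()),
        poly_s_edited=int((syn & is_edited & is_poly).sum()),
        poly_n_edited=int((nonsyn & is_edited & is_poly).sum()),
    )


def binomial_excess_test(k: int, n: int, neutral_rate: float) -> float:
    """One-sided binomial p-value P(X ≥ k), X ~ Binomial(n, neutral_rate)."""
    if not 0 < neutral_rate < 1:
        raise ValueError("neutral_rate must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, neutral_rate))
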