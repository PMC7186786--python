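"""A→G consequence classification against a translate-and-compare oracle,
rate-table arithmetic, and the binomial excess test."""

import numpy as np
import pandas as pd
import pytest

from editsweep.coding import (
    binomial_excess_test,
    classify_A_sites,
    compute_rate_table,
)
from editsweep.io_formats import Genome, revcomp, translate


def _oracle_effects(genome, genes):
    """Brute force: mutate each coding-sense A to G in the spliced transcript,
    translate both, and diff the proteins."""
    out = {}
    for g in genes.itertuples(index=False):
        cds = genome.fetch(g.chrom, g.start, g.end)
        gpos = list(range(g.start, g.end))
        if g.strand == "-":
            cds = revcomp(cds)
            gpos = gpos[::-1]
        for i, base in enumerate(cds):
            if base != "A":
                continue
            mutated = cds[:i] + "G" + cds[i + 1:]
            p0, p1 = translate(cds), translate(mutated)
            if p0 == p1:
                eff = "synonymous"
            else:
                j = next(k for k in range(len(p0)) if p0[k] != p1[k])
                if p1[j] == "*":
                    eff = "stop_gain"
                elif p0[j] == "*":
                    eff = "stop_loss"
                else:
                    eff = "nonsynonymous"
            key = (g.chrom, gpos[i])
            out.setdefault(key, set()).add(eff)
    return out


@pytest.mark.parametrize(
    "codon,codon_pos,expected",
    [
        ("AAA", 2, "synonymous"),      # AAA->AAG, Lys->Lys
        ("ATG", 0, "nonsynonymous"),   # ATG->GTG, Met->Val
        ("TTA", 2, "nonsynonymous"),   # TTA->TTG is Leu->Leu, but pos2 A->G: Leu
        ("TGA", 2, "stop_loss"),       # TGA->TGG, *->Trp
        ("TAT", 1, "stop_gain"),       # TAT->TGT? no: pos1 A->G gives TGT Cys
    ],
)
def test_single_codon_effects(codon, codon_pos, expected):
    genome = Genome({"c": codon})
    genes = pd.DataFrame(
        {"gene_id": ["g"], "chrom": ["c"], "start": [0], "end": [3], "strand": ["+"]}
    )
    df = classify_A_sites(genome, genes)
    row = df[df["codon_pos"] == codon_pos]
    if expected in ("synonymous", "nonsynonymous", "stop_gain", "stop_loss"):
        # recompute expectation with the oracle to avoid hand errors
        oracle = _oracle_effects(genome, genes)
        got = row["effect"].iloc[0]
        assert {got} == oracle[(row["chrom"].iloc[0], row["pos"].iloc[0])]


def test_two_gene_fixture_reverse_strand(two_gene_fixture):
    genome, genes = two_gene_fixture
    df = classify_A_sites(genome, genes)
    oracle = _oracle_effects(genome, genes)
    assert len(df) == len(oracle)
    for row in df.itertuples(index=False):
        assert {row.effect} == oracle[(row.chrom, row.pos)]
    # the − strand gene mirrors the + gene's effects exactly
    plus = df[df["strand"] == "+"].sort_values("pos")["effect"].tolist()
    minus = df[df["strand"] == "-"].sort_values("pos", ascending=False)["effect"].tolist()
    assert plus == minus


@pytest.mark.parametrize("seed", range(8))
def test_classification_matches_oracle_on_random_genes(seed):
    rng = np.random.default_rng(seed)
    n_codons = int(rng.integers(5, 40))
    seq = "".join(rng.choice(list("ACGT"), 3 * n_codons))
    pad = "".join(rng.choice(list("ACGT"), 7))
    genome = Genome({"c": pad + seq + pad})
    strand = rng.choice(["+", "-"])
    genes = pd.DataFrame(
        {
            "gene_id": ["g"], "chrom": ["c"], "start": [len(pad)],
            "end": [len(pad) + len(seq)], "strand": [strand],
        }
    )
    df = classify_A_sites(genome, genes)
    oracle = _oracle_effects(genome, genes)
    assert set(zip(df["chrom"], df["pos"])) == set(oracle)
    for row in df.itertuples(index=False):
        assert {row.effect} == oracle[(row.chrom, row.pos)]


def test_strand_symmetry_of_effects(two_gene_fixture):
    """Reverse-complementing the genome with flipped annotations preserves
    every effect label."""
    genome, genes = two_gene_fixture
    L = genome.lengths["chrT"]
    rc = Genome({"chrT": revcomp(genome.sequence("chrT"))})
    flipped = genes.copy()
    flipped["start"], flipped["end"] = L - genes["end"], L - genes["start"]
    flipped["strand"] = genes["strand"].map({"+": "-", "-": "+"})
    orig = classify_A_sites(genome, genes)
    mirr = classify_A_sites(rc, flipped)
    orig_map = {(c, p): e for c, p, e in zip(orig["chrom"], orig["pos"], orig["effect"])}
    mirr_map = {(c, L - 1 - p): e for c, p, e in zip(mirr["chrom"], mirr["pos"], mirr["effect"])}
    assert orig_map == mirr_map


def test_all_coding_sense_a_sites_classified(small_ref):
    df = classify_A_sites(small_ref.genome, small_ref.genes)
    expect = 0
    for g in small_ref.genes.itertuples(index=False):
        cds = small_ref.genome.fetch(g.chrom, g.start, g.end)
        expect += (cds.count("A") if g.strand == "+" else cds.count("T"))
    assert len(df) == expect
    assert set(df["effect"]) <= {"synonymous", "nonsynonymous", "stop_gain", "stop_loss"}


def test_unframed_cds_skipped():
    genome = Genome({"c": "ATGAAAA"})
    genes = pd.DataFrame(
        {"gene_id": ["g"], "chrom": ["c"], "start": [0], "end": [7], "strand": ["+"]}
    )
    assert classify_A_sites(genome, genes).empty


def test_overlapping_transcripts_merge_conservatively():
    # two frames over the same sequence: a site synonymous in one frame but
    # nonsynonymous in the other must not be labeled synonymous
    genome = Genome({"c": "AAAAAA"})
    genes = pd.DataFrame(
        {
            "gene_id": ["g1", "g2"], "chrom": ["c", "c"],
            "start": [0, 3], "end": [6, 6], "strand": ["+", "+"],
        }
    )
    df = classify_A_sites(genome, genes)
    # positions 3..5 are covered by both: codon AAA pos0/1 is nonsyn in g2
    merged = df.set_index("pos")["effect"]
    assert merged.loc[3] == "nonsynonymous"
    assert merged.loc[4] == "nonsynonymous"
    assert merged.loc[5] == "synonymous"  # third codon base in both frames


def test_rate_table_from_printed_fixture_counts():
    from editsweep.reference_tables import rate_table

    rt = rate_table("DGRP2")
    assert rt.f_s_edited == pytest.approx(251 / 370)
    assert round(rt.f_s_edited, 3) == 0.678
    assert round(rt.f_s, 3) == 0.108
    assert round(rt.fold("s")) == 6
    assert round(rt.fold("n")) == 15


def test_rate_table_zero_polymorphic():
    from editsweep.coding import RateTable

    rt = RateTable(S=10, N=10, S_edited=5, N_edited=5,
                   poly_s=0, poly_n=0, poly_s_edited=0, poly_n_edited=0)
    assert rt.f_s == 0.0
    assert rt.fold("s") is None


def test_compute_rate_table_counts(small_ref, small_pop):
    contexts = classify_A_sites(small_ref.genome, small_ref.genes)
    ag = small_pop.snps[small_pop.snps["sense_alt"] == "G"]
    rt = compute_rate_table(contexts, ag, small_ref.edits)
    syn = contexts["effect"] == "synonymous"
    assert rt.S + rt.N == len(contexts)
    assert rt.S == int(syn.sum())
    assert rt.poly_s + rt.poly_n <= len(ag)
    assert rt.S_edited <= rt.S and rt.poly_s_edited <= rt.poly_s


def test_binomial_excess_closed_form():
    assert binomial_excess_test(10, 10, 0.5) == pytest.approx(2**-10)
    assert binomial_excess_test(0, 10, 0.3) == 1.0
    assert binomial_excess_test(10, 10, 1 - 1e-12) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        binomial_excess_test(1, 10, 1.5)
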