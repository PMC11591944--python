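"""Promoter windows and Match-style PWM scanning."""

import numpy as np
import pandas as pd
import pytest

from snp2tf.motifs import (
    consensus_to_pwm,
    extract_promoters,
    match_scan,
    pwm_information,
    resolve_overlaps,
    reverse_complement,
)
from snp2tf.simulate import MotifPlantConfig, decoy_pwms, plant_promoters


def _prom(seq, gene="g1"):
    return pd.DataFrame(
        {"gene_id": [gene], "sequence": [seq], "truncated": [False]}
    )


class TestExtractPromoters:
    def test_truncated_at_contig_edge(self):
        genes = pd.DataFrame(
            [("g1", "1", 300, 900, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )
        genome = {"1": "A" * 2000}
        out = extract_promoters(genes, genome)
        assert out.loc[0, "truncated"]
        assert len(out.loc[0, "sequence"]) == 399  # 299 upstream + 100 down

    def test_strand_symmetric_fixture(self):
        """+ and - strand genes anchored on the same TSS base give reverse
        complementary windows."""
        rng = np.random.default_rng(0)
        contig = "".join(rng.choice(list("ACGT"), size=3000))
        genes = pd.DataFrame(
            [("plus", "1", 1501, 2200, "+"), ("minus", "1", 900, 1501, "-")],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )
        out = extract_promoters(genes, {"1": contig}).set_index("gene_id")
        plus = out.loc["plus", "sequence"]
        minus = out.loc["minus", "sequence"]
        assert len(plus) == len(minus) == 600
        # the two windows overlap on genome bases 1401..1599; in promoter
        # coordinates that is [401, 600) of both, read from opposite strands
        assert plus[401:600] == reverse_complement(minus[401:600])

    def test_unknown_contig_raises(self):
        genes = pd.DataFrame(
            [("g1", "9", 1000, 2000, "+")],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )
        with pytest.raises(KeyError):
            extract_promoters(genes, {"1": "A" * 5000})


class TestPWMInformation:
    def test_uniform_column_zero(self):
        assert pwm_information(np.array([[0.25, 0.25, 0.25, 0.25]]))[0] == pytest.approx(0.0)

    def test_degenerate_column_ln4(self):
        assert pwm_information(np.array([[1.0, 0, 0, 0]]))[0] == pytest.approx(np.log(4))

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        f = rng.dirichlet(np.ones(4), size=12)
        direct = np.array(
            [sum(p * np.log(4 * p) for p in row if p > 0) for row in f]
        )
        assert np.allclose(pwm_information(f), direct, atol=1e-12)


class TestMatchScan:
    def test_consensus_scores_exactly_one(self):
        for consensus in ("TATAAT", "GGGCGGAA", "ACGTACGT"):
            pwm = consensus_to_pwm(consensus, 0.1)
            hits = match_scan(_prom(consensus), [pwm], mss_cutoff=0.0, css_cutoff=0.0)
            fwd = hits[hits.strand == "+"]
            assert fwd["mss"].max() == pytest.approx(1.0, abs=0.0)

    def test_anti_consensus_scores_zero(self):
        pwm = consensus_to_pwm("AAAA", 0.1)
        hits = match_scan(_prom("CCCC"), [pwm], mss_cutoff=-0.1, css_cutoff=-0.1)
        fwd = hits[hits.strand == "+"]
        assert fwd["mss"].min() == pytest.approx(0.0, abs=1e-12)

    def test_planted_recall_is_total(self):
        cfg = MotifPlantConfig(n_promoters=30, motif_pairs=[("TATAATAA", "GGGCGGAA")],
                               plant_fraction=1.0, seed=5)
        seqs, truth = plant_promoters(cfg)
        promoters = pd.DataFrame(
            {"gene_id": list(seqs), "sequence": list(seqs.values()),
             "truncated": False}
        )
        pwms = [consensus_to_pwm("TATAATAA", 0.0, matrix_id="A", tf_name="A"),
                consensus_to_pwm("GGGCGGAA", 0.0, matrix_id="B", tf_name="B")]
        hits = match_scan(promoters, pwms, mss_cutoff=0.95, css_cutoff=0.90)
        found = set(zip(hits["gene_id"], hits["start"], hits["end"]))
        for rec in truth.itertuples(index=False):
            assert (rec.chrom, rec.start, rec.end) in found

    def test_background_false_hit_rate(self):
        """Sharp PWMs on pure background: < 1e-2 hits per kb per PWM at 0.95."""
        cfg = MotifPlantConfig(n_promoters=100, plant_fraction=0.0, seed=6)
        seqs, _ = plant_promoters(cfg)
        promoters = pd.DataFrame(
            {"gene_id": list(seqs), "sequence": list(seqs.values()), "truncated": False}
        )
        pwms = decoy_pwms(5, length=10, seed=7)
        hits = match_scan(promoters, pwms, mss_cutoff=0.95, css_cutoff=0.90)
        kb = 100 * 600 / 1000
        assert len(hits) / (kb * len(pwms)) < 1e-2

    def test_strand_symmetry(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        pwm = consensus_to_pwm("TGACTCA", 0.2)
        fwd = match_scan(_prom(seq), [pwm], mss_cutoff=0.7, css_cutoff=0.6)
        rev = match_scan(_prom(reverse_complement(seq)), [pwm],
                         mss_cutoff=0.7, css_cutoff=0.6)
        L = len(seq)
        mirrored = {
            (L - r.end, L - r.start, {"+": "-", "-": "+"}[r.strand], round(r.mss, 9))
            for r in rev.itertuples(index=False)
        }
        original = {
            (r.start, r.end, r.strand, round(r.mss, 9))
            for r in fwd.itertuples(index=False)
        }
        assert mirrored == original

    def test_n_windows_skipped(self):
        pwm = consensus_to_pwm("AAAA", 0.1)
        hits = match_scan(_prom("AANAAAAA"), [pwm], mss_cutoff=0.5, css_cutoff=0.5)
        assert (hits["start"] >= 3).all()

    def test_pwm_longer_than_promoter_warns(self):
        pwm = consensus_to_pwm("A" * 30, 0.1)
        with pytest.warns(UserWarning, match="longer"):
            hits = match_scan(_prom("ACGTACGT"), [pwm], 0.5, 0.5)
        assert hits.empty


class TestResolveOverlaps:
    def _hits(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "tf", "matrix_id", "start", "end", "strand", "mss"]
        )

    def test_identical_intervals_keep_best(self):
        hits = self._hits(
            [("g", "TF1", "M", 10, 20, "+", 0.97), ("g", "TF1", "M", 10, 20, "-", 0.99)]
        )
        out = resolve_overlaps(hits)
        assert len(out) == 1 and out["mss"].iloc[0] == 0.99

    def test_adjacent_non_overlapping_kept(self):
        hits = self._hits(
            [("g", "TF1", "M", 10, 20, "+", 0.97), ("g", "TF1", "M", 20, 30, "+", 0.96)]
        )
        assert len(resolve_overlaps(hits)) == 2

    def test_forty_percent_overlap_kept(self):
        hits = self._hits(
            [("g", "TF1", "M", 0, 10, "+", 0.97), ("g", "TF1", "M", 6, 16, "+", 0.96)]
        )
        assert len(resolve_overlaps(hits)) == 2

    def test_different_tfs_never_collapsed(self):
        hits = self._hits(
            [("g", "TF1", "M1", 10, 20, "+", 0.97), ("g", "TF2", "M2", 10, 20, "+", 0.99)]
        )
        assert len(resolve_overlaps(hits)) == 2
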