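"""Generative behaviour of the codon simulator against its stated moments."""

import numpy as np
import pytest
from scipy import stats as sps

from httscan import simulate
from httscan.codon_stats import ds_ng86, enc, k2p

TREE2 = "(donor:10,recipient:10);"


def _cfg(**kw):
    kw.setdefault("species_tree", TREE2)
    kw.setdefault("seed", 0)
    return simulate.SimConfig(**kw)


class TestGeneProcess:
    def test_zero_bias_gives_near_maximal_enc(self):
        cfg = _cfg()
        rng = simulate.unit_rng(0, "enc0")
        tips, _ = simulate.simulate_gene(0.0, TREE2, cfg, rng)
        assert enc(tips["donor"]).Nc > 58.0

    def test_measured_enc_decreases_with_beta(self):
        cfg = _cfg()
        means = []
        for beta in (0.0, 0.3, 0.6, 0.9):
            ncs = []
            for rep in range(5):
                rng = simulate.unit_rng(0, f"b{beta}r{rep}")
                tips, _ = simulate.simulate_gene(beta, TREE2, cfg, rng)
                ncs.append(enc(tips["donor"]).Nc)
            means.append(np.mean(ncs))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_expected_enc_matches_root_draw_at_long_sequences(self):
        # at the root the codon distribution is exactly the preference
        # distribution; along branches the realized bias erodes slightly
        cfg = _cfg(codons_per_gene=5000)
        rng = simulate.unit_rng(0, "enclong")
        tips, _ = simulate.simulate_gene(
            0.5, "(donor:0.001,recipient:0.001);", cfg, rng)
        assert enc(tips["donor"]).Nc == pytest.approx(
            simulate.expected_enc(0.5), abs=1.5
        )

    def test_mean_ds_matches_poisson_expectation(self):
        # two tips split 10 My ago at r_max=0.02: expected dS ~ 2*0.02*10
        cfg = _cfg()
        ds = []
        for rep in range(100):
            rng = simulate.unit_rng(1, f"ds{rep}")
            tips, _ = simulate.simulate_gene(0.0, TREE2, cfg, rng)
            ds.append(ds_ng86(tips["donor"], tips["recipient"]).dS)
        assert np.mean(ds) == pytest.approx(0.4, rel=0.10)

    def test_rate_slows_with_bias(self):
        cfg = _cfg()
        truth_low = simulate.simulate_gene(
            0.0, TREE2, cfg, simulate.unit_rng(0, "a"))[1]
        truth_high = simulate.simulate_gene(
            0.9, TREE2, cfg, simulate.unit_rng(0, "b"))[1]
        assert truth_high.r_s < truth_low.r_s
        assert truth_low.r_s == pytest.approx(cfg.r_max)

    def test_protein_sequence_invariant_across_tips(self):
        from httscan.codon_stats import CODON_TO_AA
        cfg = _cfg()
        tips, _ = simulate.simulate_gene(0.4, TREE2, cfg,
                                         simulate.unit_rng(0, "aa"))
        translate = lambda s: "".join(
            CODON_TO_AA[s[i:i + 3]] for i in range(0, len(s), 3)
        )
        assert translate(tips["donor"]) == translate(tips["recipient"])


class TestTeProcess:
    def test_transfer_at_time_zero_gives_identical_copies(self):
        cfg = _cfg()
        spec = simulate.TeSpec(unit_id="t0", mode="horizontal",
                               donor="donor", recipient="recipient",
                               t_ht_my=0.0, beta=0.2)
        tips, truth = simulate.simulate_te(spec, TREE2, cfg,
                                           simulate.unit_rng(0, "t0"))
        assert tips["donor"] == tips["recipient"]
        assert truth.t_ht_my == 0.0

    def test_recent_transfer_divergence_far_below_vertical(self):
        cfg = _cfg()
        spec = simulate.TeSpec(unit_id="t1", mode="horizontal",
                               donor="donor", recipient="recipient",
                               t_ht_my=1.0, beta=0.0)
        ds_h = []
        for rep in range(30):
            tips, _ = simulate.simulate_te(
                spec, TREE2, cfg, simulate.unit_rng(rep, "t1"))
            ds_h.append(ds_ng86(tips["donor"], tips["recipient"]).dS)
        # expected ~ 2 * 0.02 * 1 = 0.04 against a vertical 0.4
        assert np.mean(ds_h) == pytest.approx(0.04, rel=0.25)

    def test_vertical_te_looks_like_a_gene(self):
        cfg = _cfg(codons_per_te=500)
        spec = simulate.TeSpec(unit_id="tv", mode="vertical", beta=0.3)
        ds_te, ds_gene = [], []
        for rep in range(40):
            tips, _ = simulate.simulate_te(
                spec, TREE2, cfg, simulate.unit_rng(rep, "tv"))
            ds_te.append(ds_ng86(tips["donor"], tips["recipient"]).dS)
            gtips, _ = simulate.simulate_gene(
                0.3, TREE2, cfg, simulate.unit_rng(rep, "gv"))
            ds_gene.append(ds_ng86(gtips["donor"], gtips["recipient"]).dS)
        assert np.mean(ds_te) == pytest.approx(np.mean(ds_gene), rel=0.1)

    def test_unknown_recipient_raises(self):
        spec = simulate.TeSpec(unit_id="x", mode="horizontal",
                               donor="donor", recipient="martian",
                               t_ht_my=1.0)
        with pytest.raises(ValueError, match="martian"):
            simulate.simulate_te(spec, TREE2, _cfg(),
                                 simulate.unit_rng(0, "x"))

    def test_transfer_time_must_precede_divergence(self):
        spec = simulate.TeSpec(unit_id="x", mode="horizontal",
                               donor="donor", recipient="recipient",
                               t_ht_my=50.0)
        with pytest.raises(ValueError, match="depth"):
            simulate.simulate_te(spec, TREE2, _cfg(),
                                 simulate.unit_rng(0, "x"))


class TestCopyBurst:
    def test_age_zero_copies_identical(self):
        rng = np.random.default_rng(0)
        copies = simulate.simulate_copy_burst("ACGT" * 100, 0.0, 0.01, 5, rng)
        assert all(c == "ACGT" * 100 for c in copies)

    def test_mean_k2p_matches_rate_times_age(self):
        rng = np.random.default_rng(1)
        consensus = "".join(rng.choice(list("ACGT"), 1800))
        copies = simulate.simulate_copy_burst(consensus, 5.0, 0.004, 50, rng)
        ks = [k2p(c, consensus).K for c in copies]
        assert np.mean(ks) == pytest.approx(0.02, rel=0.15)

    def test_transition_bias_shows_in_p_over_q(self):
        rng = np.random.default_rng(2)
        consensus = "".join(rng.choice(list("ACGT"), 3000))
        copies = simulate.simulate_copy_burst(consensus, 5.0, 0.01, 30, rng,
                                              kappa=2.0)
        p = sum(k2p(c, consensus).p for c in copies)
        q = sum(k2p(c, consensus).q for c in copies)
        # kappa=2: each event is a transition with prob 1/2 -> p/q ~ 1
        assert 0.8 < p / q < 1.25


class TestStudyBundle:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = _cfg(n_genes=3, codons_per_gene=60, codons_per_te=60,
                   te_specs=[simulate.TeSpec(unit_id="te1", mode="vertical",
                                             beta=0.5)])
        a, b = tmp_path / "a", tmp_path / "b"
        simulate.generate_study(cfg, a)
        simulate.generate_study(cfg, b)
        files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_adding_units_does_not_perturb_existing_ones(self, tmp_path):
        base = _cfg(n_genes=2, codons_per_gene=60)
        more = _cfg(n_genes=2, codons_per_gene=60,
                    te_specs=[simulate.TeSpec(unit_id="te1", mode="vertical")])
        a, b = tmp_path / "a", tmp_path / "b"
        simulate.generate_study(base, a)
        simulate.generate_study(more, b)
        assert (a / "genes" / "gene_0000.fa").read_bytes() == \
            (b / "genes" / "gene_0000.fa").read_bytes()

    def test_zero_te_config_gives_genes_only_bundle(self, tmp_path):
        cfg = _cfg(n_genes=2, codons_per_gene=60)
        out = simulate.generate_study(cfg, tmp_path / "s")
        assert not list((out / "tes").glob("*.fa"))
        assert len(list((out / "genes").glob("*.fa"))) == 2

    def test_bundle_parses_through_io_formats(self, small_study):
        from httscan.io_formats import (read_blast_tab, read_divergence_table,
                                        read_fasta)
        _, outdir = small_study
        assert read_fasta(outdir / "genome.fa")
        assert read_blast_tab(outdir / "hits.tsv")
        assert read_divergence_table(outdir / "divergence.tsv")
        for fasta in (outdir / "genes").glob("*.fa"):
            recs = read_fasta(fasta)
            assert len({len(s) for _, s in recs}) == 1  # aligned


class TestConfigValidation:
    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            _cfg(lambda_cub=1.0)

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            simulate.TeSpec(unit_id="x", mode="sideways")

    def test_tree_without_branch_lengths(self):
        with pytest.raises(ValueError, match="branch lengths"):
            simulate.simulate_gene(0.1, "(a,b);", _cfg(),
                                   simulate.unit_rng(0, "x"))


def test_enc_rank_correlation_with_beta_is_negative():
    cfg = _cfg()
    betas = np.linspace(0, 0.95, 12)
    ncs = []
    for i, beta in enumerate(betas):
        tips, _ = simulate.simulate_gene(
            float(beta), TREE2, cfg, simulate.unit_rng(0, f"grid{i}"))
        ncs.append(enc(tips["donor"]).Nc)
    rho, _ = sps.spearmanr(betas, ncs)
    assert rho < -0.9
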