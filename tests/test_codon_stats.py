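"""dS (NG86), ENC and K2P against independent oracles and closed forms."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from httscan.codon_stats import (
    CODON_TO_AA,
    ds_ng86,
    enc,
    family_k2p_profile,
    k2p,
)

BASES = "ACGT"
SENSE_CODONS = [c for c in map("".join, product(BASES, repeat=3))
                if CODON_TO_AA[c] != "*"]


# ---------------------------------------------------------------------------
# independent NG86 oracle: recomputed from the genetic code, enumeration only


def oracle_syn_sites(codon):
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos, base in product(range(3), BASES):
        if base == codon[pos]:
            continue
        mut = codon[:pos] + base + codon[pos + 1:]
        if CODON_TO_AA[mut] == aa:
            syn += 1
    return syn / 3.0


def oracle_differences(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    valid, fallback = [], []
    for order in permutations(diff):
        cur, sd, nd, bad = c1, 0, 0, False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TO_AA[nxt] == "*" and step < len(order) - 1:
                bad = True
            if CODON_TO_AA[nxt] != "*" and CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        fallback.append((sd, nd))
        if not bad:
            valid.append((sd, nd))
    use = valid or fallback
    return (sum(s for s, _ in use) / len(use),
            sum(n for _, n in use) / len(use))


def oracle_ds(seq1, seq2):
    S = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if CODON_TO_AA.get(c1, "*") == "*" or CODON_TO_AA.get(c2, "*") == "*":
            continue
        n_codons += 1
        S += (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2.0
        sd, nd = oracle_differences(c1, c2)
        Sd += sd
        Nd += nd
    N = 3.0 * n_codons - S
    pS, pN = Sd / S, Nd / N
    return S, N, Sd, Nd, pS, pN


class TestDsNg86:
    def test_identical_sequences_have_zero_ds(self):
        d = ds_ng86("GGT" * 10, "GGT" * 10)
        assert d.dS == 0.0 and d.dN == 0.0

    def test_hand_counted_single_synonymous_change(self):
        d = ds_ng86("GGT" * 10, "GGT" * 9 + "GGC")
        assert d.S == pytest.approx(10.0)
        assert d.Sd == pytest.approx(1.0)
        assert d.pS == pytest.approx(0.1)
        assert d.dS == pytest.approx(-0.75 * math.log(1 - 4 * 0.1 / 3))
        assert d.dS == pytest.approx(0.10733, abs=1e-5)

    def test_nonsynonymous_only_change(self):
        # GGT (Gly) -> GTT (Val): first-position-adjacent nonsynonymous
        d = ds_ng86("GGT" * 10, "GGT" * 9 + "GTT")
        assert d.dS == 0.0 and d.dN > 0.0

    def test_matches_enumeration_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(120):
            n = int(rng.integers(3, 30))
            s1 = "".join(rng.choice(SENSE_CODONS, n))
            s2 = "".join(rng.choice(SENSE_CODONS, n))
            d = ds_ng86(s1, s2)
            S, N, Sd, Nd, pS, pN = oracle_ds(s1, s2)
            assert d.S == pytest.approx(S, abs=1e-9)
            assert d.N == pytest.approx(N, abs=1e-9)
            assert d.Sd == pytest.approx(Sd, abs=1e-9)
            assert d.Nd == pytest.approx(Nd, abs=1e-9)

    def test_site_count_partition(self):
        rng = np.random.default_rng(1)
        s1 = "".join(rng.choice(SENSE_CODONS, 50))
        d = ds_ng86(s1, s1)
        assert d.S + d.N == pytest.approx(3 * 50)

    def test_saturation_flagged(self):
        # maximally divergent synonymous codons everywhere
        d = ds_ng86("GGT" * 30, "GGA" * 30)
        assert d.pS == 1.0 and d.saturated and math.isnan(d.dS)

    def test_gap_and_n_codons_skipped_pairwise(self):
        d = ds_ng86("GGTNNNGGC", "GGT---GGT")
        assert d.n_codons == 2
        assert d.Sd == pytest.approx(1.0)

    def test_no_comparable_codons_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            ds_ng86("NNN", "ACG")

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        s1 = "".join(rng.choice(SENSE_CODONS, 20))
        s2 = "".join(rng.choice(SENSE_CODONS, 20))
        a, b = ds_ng86(s1, s2), ds_ng86(s2, s1)
        assert a.Sd == b.Sd and a.S == b.S and a.pN == b.pN

    def test_agrees_with_biopython_ng86_below_saturation(self):
        """Independent cross-check: Biopython's NG86 implementation gives
        machine-identical dS/dN at unsaturated divergence."""
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(11)
        for _ in range(15):
            s1 = list(rng.choice(SENSE_CODONS, 100))
            s2 = list(s1)
            for pos in rng.choice(100, 8, replace=False):
                for _ in range(10):  # a single-nucleotide codon change
                    c = str(rng.choice(SENSE_CODONS))
                    if sum(a != b for a, b in zip(c, s2[pos])) == 1:
                        s2[pos] = c
                        break
            s1, s2 = "".join(s1), "".join(s2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
            d = ds_ng86(s1, s2)
            assert d.dS == pytest.approx(ds, abs=1e-12)
            assert d.dN == pytest.approx(dn, abs=1e-12)

    def test_jc_correction_monotone_in_differences(self):
        base = "GGT" * 20
        prev = -1.0
        for k in range(0, 8):
            other = "GGC" * k + "GGT" * (20 - k)
            d = ds_ng86(base, other)
            assert d.dS > prev
            prev = d.dS


class TestEnc:
    def test_uniform_usage_gives_61(self):
        seq = "".join(c * 10 for c in SENSE_CODONS)
        assert enc(seq).Nc == pytest.approx(61.0)

    def test_single_codon_per_amino_acid_gives_20(self):
        chosen = {}
        for c in SENSE_CODONS:
            chosen.setdefault(CODON_TO_AA[c], c)
        seq = "".join(c * 5 for c in chosen.values())
        assert enc(seq).Nc == pytest.approx(20.0)

    def test_matches_direct_homozygosity_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(rng.choice(SENSE_CODONS, 500))
            got = enc(seq).Nc

            counts = {}
            for i in range(0, len(seq), 3):
                counts[seq[i:i + 3]] = counts.get(seq[i:i + 3], 0) + 1
            fams = {}
            for c in SENSE_CODONS:
                fams.setdefault(CODON_TO_AA[c], []).append(c)
            f_class = {2: [], 3: [], 4: [], 6: []}
            for aa, cods in fams.items():
                if len(cods) == 1:
                    continue
                n = sum(counts.get(c, 0) for c in cods)
                if n < 2:
                    continue
                s = sum((counts.get(c, 0) / n) ** 2 for c in cods)
                f = (n * s - 1) / (n - 1)
                if f > 0:
                    f_class[len(cods)].append(f)
            fbar = {k: sum(v) / len(v) for k, v in f_class.items() if v}
            expected = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
            expected = min(61.0, max(20.0, expected))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            enc("")


class TestK2p:
    def test_identical_sequences(self):
        r = k2p("ACGT" * 10, "ACGT" * 10)
        assert (r.p, r.q, r.K) == (0.0, 0.0, 0.0)

    def test_closed_form_value(self):
        # 100 sites: 10 transitions, 5 transversions -> p=0.1, q=0.05
        s1 = "A" * 100
        s2 = "G" * 10 + "C" * 5 + "A" * 85
        r = k2p(s1, s2)
        assert (r.p, r.q) == (0.1, 0.05)
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert r.K == pytest.approx(expected)
        assert r.K == pytest.approx(0.1702, abs=2e-4)

    def test_transversion_saturation_flagged(self):
        s1 = "A" * 100
        s2 = "C" * 50 + "A" * 50  # q = 0.5
        r = k2p(s1, s2)
        assert r.saturated and math.isnan(r.K)

    def test_gapped_columns_excluded(self):
        r = k2p("AC-GT", "ACNGA")
        assert r.n_sites == 4  # the gap/N column is dropped
        assert r.p == 0.0
        assert r.q == pytest.approx(0.25)  # T/A is a transversion

    def test_k_monotone_in_transitions_at_fixed_transversions(self):
        prev = -1.0
        for nts in range(0, 20):
            s2 = "G" * nts + "C" * 5 + "A" * (95 - nts)
            r = k2p("A" * 100, s2)
            assert r.K > prev
            prev = r.K

    def test_reduces_toward_p_plus_q_for_small_divergence(self):
        s1 = "A" * 10_000
        s2 = "G" * 10 + "C" * 10 + "A" * 9_980
        r = k2p(s1, s2)
        assert r.K == pytest.approx(r.p + r.q, rel=5e-3)


class TestFamilyProfile:
    def test_identical_copies_have_zero_mean(self):
        consensus = "ACGT" * 100
        prof = family_k2p_profile([("c1", consensus), ("c2", consensus)],
                                  consensus)
        assert prof["mean"] == 0.0 and prof["median"] == 0.0

    def test_mean_and_median_of_two_copies(self):
        rng = np.random.default_rng(5)
        consensus = "".join(rng.choice(list("ACGT"), 600))

        def mutate(seq, n):
            out = list(seq)
            for pos in rng.choice(600, size=n, replace=False):
                out[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[out[pos]]
            return "".join(out)

        near = mutate(consensus, 30)
        far = mutate(consensus, 120)
        prof = family_k2p_profile([("a", near), ("b", far)], consensus)
        ks = dict(prof["per_copy"])
        assert ks["a"] < ks["b"]
        assert prof["mean"] == pytest.approx((ks["a"] + ks["b"]) / 2)
        assert prof["median"] == prof["mean"]

    def test_no_copies_raises(self):
        with pytest.raises(ValueError):
            family_k2p_profile([], "ACGT")
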