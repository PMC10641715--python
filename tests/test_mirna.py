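"""miRNA target scoring: penalty scheme, window scan, enrichment test."""

import itertools

import numpy as np
import pytest

from rgenescape.mirna import (
    DEFAULT_SCHEME,
    ScoringScheme,
    best_site,
    chisq_2x2,
    predict_targets,
    score_site,
)

MIR = "UCUUCCCUACUCCUCCCAUUCC"  # miR482-like, 22 nt

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def perfect_site(mir=MIR):
    return revcomp(mir)


def mutate_site_at_mirna_pos(site, mirna_pos_1based, kind):
    """Perturb the site base paired with the given miRNA position.

    kind "mismatch": a base that is neither complementary nor wobble;
    kind "wobble": mRNA U facing miRNA G (or mRNA G facing miRNA U).
    """
    i = len(site) - mirna_pos_1based  # site index pairing miRNA position p
    m = MIR[mirna_pos_1based - 1]
    if kind == "wobble":
        assert m in "GU", "wobble needs miRNA G or U at that position"
        new = "U" if m == "G" else "G"
    else:
        complement = _COMP[m]
        wobble_partner = {"G": "U", "U": "G"}.get(m)
        new = next(b for b in "ACGU" if b not in (complement, wobble_partner, None))
    return site[:i] + new + site[i + 1 :]


def oracle_score(mirna, site, scheme=DEFAULT_SCHEME):
    """Independent gapless+1-gap alignment enumerator (explicit pairing)."""
    mirna = mirna.upper().replace("T", "U")
    site = site.upper().replace("T", "U")

    def pair_pen(m, t):  # miRNA base vs mRNA base
        if _COMP[m] == t:
            return 0.0
        if (m, t) in (("G", "U"), ("U", "G")):
            return scheme.wobble
        return scheme.mismatch

    def weight(p):
        return scheme.seed_multiplier if scheme.seed_start <= p <= scheme.seed_end else 1.0

    # pair miRNA position p (1-based, 5'->3') with site base site[len-p] (+ shifts for gaps)
    tgt = site[::-1]  # 3'->5' of the site aligns along the miRNA 5'->3'
    lm, lt = len(mirna), len(tgt)
    scores = []
    if lm == lt:
        scores.append(sum(pair_pen(mirna[p], tgt[p]) * weight(p + 1) for p in range(lm)))
    elif lt == lm + 1:
        for skip in range(lt):
            s = scheme.gap * weight(min(skip, lm - 1) + 1)
            for p in range(lm):
                s += pair_pen(mirna[p], tgt[p if p < skip else p + 1]) * weight(p + 1)
            scores.append(s)
    elif lt == lm - 1:
        for skip in range(lm):
            s = scheme.gap * weight(skip + 1)
            for p in range(lm):
                if p == skip:
                    continue
                s += pair_pen(mirna[p], tgt[p if p < skip else p - 1]) * weight(p + 1)
            scores.append(s)
    return min(scores)


def oracle_best(mirna, cds, scheme=DEFAULT_SCHEME):
    lm = len(mirna)
    best = float("inf")
    for wlen in (lm - 1, lm, lm + 1):
        if wlen < 1 or wlen > len(cds):
            continue
        for start in range(len(cds) - wlen + 1):
            best = min(best, oracle_score(mirna, cds[start : start + wlen], scheme))
    return best


class TestScoreSite:
    def test_perfect_reverse_complement_scores_zero(self):
        assert score_site(MIR, perfect_site()) == 0.0

    def test_non_seed_mismatch_scores_one(self):
        site = mutate_site_at_mirna_pos(perfect_site(), 15, "mismatch")
        assert score_site(MIR, site) == pytest.approx(1.0)

    def test_seed_wobble_scores_three_quarters(self):
        # miRNA position 5 is a C in MIR; use position 4 (U) for a wobble
        pos = next(p for p in range(2, 14) if MIR[p - 1] in "GU")
        site = mutate_site_at_mirna_pos(perfect_site(), pos, "wobble")
        assert score_site(MIR, site) == pytest.approx(0.75)

    def test_seed_mismatch_scores_one_point_five(self):
        site = mutate_site_at_mirna_pos(perfect_site(), 5, "mismatch")
        assert score_site(MIR, site) == pytest.approx(1.5)

    def test_any_mismatch_strictly_increases_score(self):
        site = perfect_site()
        for pos in range(1, len(MIR) + 1):
            mutated = mutate_site_at_mirna_pos(site, pos, "mismatch")
            assert score_site(MIR, mutated) > 0.0

    def test_zero_iff_perfect(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            site = "".join(rng.choice(list("ACGU"), size=len(MIR)))
            expected_zero = site == perfect_site()
            assert (score_site(MIR, site) == 0.0) == expected_zero

    def test_gapped_site_lengths_accepted(self):
        site = perfect_site()
        bulged = site[:10] + "A" + site[10:]       # one extra target base
        assert score_site(MIR, bulged) >= DEFAULT_SCHEME.gap * 1.0
        shrunk = site[:10] + site[11:]             # one missing target base
        assert score_site(MIR, shrunk) >= DEFAULT_SCHEME.gap * 1.0

    def test_length_mismatch_beyond_one_gap_rejected(self):
        with pytest.raises(ValueError):
            score_site(MIR, perfect_site()[:-2])

    def test_matches_alignment_oracle_on_random_sites(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            wlen = len(MIR) + int(rng.integers(-1, 2))
            site = "".join(rng.choice(list("ACGU"), size=wlen))
            assert score_site(MIR, site) == pytest.approx(oracle_score(MIR, site))


class TestPredictTargets:
    def _fastas(self, tmp_path, cds_records, mirnas=None):
        mir_path = tmp_path / "mir.fa"
        mir_path.write_text(
            "".join(f">{mid}\n{seq}\n" for mid, seq in (mirnas or [("miR482", MIR)]))
        )
        cds_path = tmp_path / "cds.fa"
        cds_path.write_text("".join(f">{gid}\n{seq}\n" for gid, seq in cds_records))
        return mir_path, cds_path

    def test_planted_perfect_site_found(self, tmp_path):
        rng = np.random.default_rng(2)
        flank = lambda n: "".join(rng.choice(list("ACGU"), size=n))
        cds = flank(40) + perfect_site() + flank(40)
        mir_fa, cds_fa = self._fastas(tmp_path, [("gene1", cds)])
        out = predict_targets(mir_fa, cds_fa)
        assert out["expectation"].tolist() == [0.0]
        start, end = out.loc[0, ["start", "end"]]
        assert cds[start:end] == perfect_site()

    def test_planted_single_nonseed_mismatch_scores_one(self, tmp_path):
        site = mutate_site_at_mirna_pos(perfect_site(), 16, "mismatch")
        cds = "ACGU" * 10 + site + "UGCA" * 10
        mir_fa, cds_fa = self._fastas(tmp_path, [("gene1", cds)])
        out = predict_targets(mir_fa, cds_fa)
        assert len(out) == 1
        # the planted site may be beaten by a lucky flank window, never worse
        assert out.loc[0, "expectation"] <= 1.0

    def test_poor_sites_filtered_by_cutoff(self, tmp_path):
        rng = np.random.default_rng(3)
        records = []
        for i in range(5):
            records.append((f"r{i}", "".join(rng.choice(list("ACGU"), size=120))))
        mir_fa, cds_fa = self._fastas(tmp_path, records)
        out = predict_targets(mir_fa, cds_fa, max_expectation=3.0)
        full = predict_targets(mir_fa, cds_fa, max_expectation=1e9)
        assert set(out["gene_id"]) == set(
            full.loc[full["expectation"] <= 3.0, "gene_id"]
        )

    def test_window_scan_matches_oracle_on_random_cds(self, tmp_path):
        rng = np.random.default_rng(4)
        records = [
            (f"r{i}", "".join(rng.choice(list("ACGU"), size=int(rng.integers(60, 140)))))
            for i in range(15)
        ]
        mir_fa, cds_fa = self._fastas(tmp_path, records)
        out = predict_targets(mir_fa, cds_fa, max_expectation=1e9).set_index("gene_id")
        for gid, seq in records:
            assert out.loc[gid, "expectation"] == pytest.approx(oracle_best(MIR, seq))

    def test_empty_fasta_rejected(self, tmp_path):
        mir_fa, cds_fa = self._fastas(tmp_path, [("g", "ACGU" * 30)])
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(ValueError):
            predict_targets(empty, cds_fa)


class TestChisq:
    def test_worked_example(self):
        res = chisq_2x2([[30, 20], [10, 40]])
        assert res.chi2 == pytest.approx(16.667, abs=5e-4)
        assert res.dof == 1
        np.testing.assert_allclose(res.expected, [[20, 30], [20, 30]])

    def test_closed_form_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 50, size=4)
            n = a + b + c + d
            want = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chisq_2x2([[a, b], [c, d]]).chi2 == pytest.approx(want)

    def test_expected_table_gives_zero(self):
        res = chisq_2x2([[10, 20], [20, 40]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        t = [[13, 7], [5, 25]]
        assert chisq_2x2(t).chi2 == pytest.approx(chisq_2x2(np.transpose(t)).chi2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2([[0, 0], [5, 5]])

    def test_planted_enrichment_recovered(self):
        # full-length genes enriched among targets at log-OR 1.5, n = 400:
        # the association is detected at alpha = 0.05 in >= 90% of seeds
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            full = rng.random(400) < 0.5
            base_p = 0.2
            odds = base_p / (1 - base_p) * np.exp(1.5 * full)
            target = rng.random(400) < odds / (1 + odds)
            table = [
                [int((full & target).sum()), int((full & ~target).sum())],
                [int((~full & target).sum()), int((~full & ~target).sum())],
            ]
            res = chisq_2x2(table)
            a, b = table[0]
            c, d = table[1]
            if res.p_value < 0.05 and (a * d) > (b * c):
                hits += 1
        assert hits >= 0.9 * n_seeds
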