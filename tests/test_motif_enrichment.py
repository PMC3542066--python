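"""Motif grammar, window matching, and the 2D rank enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from phosvar.motif_enrichment import (
    annotate_motifs,
    enrichment_2d,
    exclude_motif_sites,
    match_motif,
    parse_motif,
    read_motif_file,
    write_motif_file,
)


class TestParseMotif:
    def test_cdk_pattern(self):
        m = parse_motif("CDK5\tpS/pT-P")
        assert dict(m.tokens)[0] == frozenset("ST")
        assert dict(m.tokens)[1] == frozenset("P")
        assert m.center_residues == frozenset("ST")

    def test_pka_pattern(self):
        m = parse_motif("PKA\tR-R-X-pS/pT")
        toks = dict(m.tokens)
        assert toks[-3] == frozenset("R")
        assert toks[-2] == frozenset("R")
        assert len(toks[-1]) == 20  # X = any residue
        assert toks[0] == frozenset("ST")

    def test_residue_set_token(self):
        m = parse_motif("CK2\tpS-X-X-[DE]")
        assert dict(m.tokens)[3] == frozenset("DE")

    def test_no_center_rejected(self):
        with pytest.raises(ValueError, match="center"):
            parse_motif("BAD\tS-T")

    def test_two_centers_rejected(self):
        with pytest.raises(ValueError, match="center"):
            parse_motif("BAD\tpS-pT")

    def test_offset_overflow_rejected(self):
        with pytest.raises(ValueError, match="offsets"):
            parse_motif("BAD\t" + "-".join(["A"] * 8) + "-pS")

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            parse_motif("BAD\tZ-pS")

    def test_non_sty_center_rejected(self):
        with pytest.raises(ValueError, match="S/T/Y"):
            parse_motif("BAD\tpA")

    def test_file_roundtrip(self, tmp_path):
        write_motif_file([("CDK", "pS/pT-P"), ("PKA", "R-R-X-pS/pT")],
                         tmp_path / "m.tsv")
        motifs = read_motif_file(tmp_path / "m.tsv")
        assert [m.name for m in motifs] == ["CDK", "PKA"]


class TestMatchMotif:
    cdk = parse_motif("CDK\tpS/pT-P")
    pka = parse_motif("PKA\tR-R-X-pS/pT")

    def test_match(self):
        assert match_motif("AAAAAASPAAAAA", self.cdk)

    def test_wrong_upstream_residue(self):
        assert not match_motif("AAAKRASPAAAAA", self.pka)  # K at -3

    def test_pka_positive(self):
        assert match_motif("AAARRASAAAAAA", self.pka)

    def test_missing_slot_fails(self):
        assert not match_motif("AAAAAAS------", self.cdk)  # P slot missing
        assert not match_motif("AAAR-ASAAAAAA", self.pka)  # -2 slot missing
        assert not match_motif("------SPAAAAA", self.pka)  # -3/-2 missing


def rank_score_oracle(values, members):
    """s = 2 (mean member midrank - (n+1)/2) / (n - m), evaluated directly."""
    r = rankdata(values)
    n, m = len(values), int(np.sum(members))
    return 2.0 * (r[members].mean() - (n + 1) / 2.0) / (n - m)


class TestEnrichment2D:
    def _run(self, x, y, members):
        mem = pd.DataFrame({"motif": members})
        return enrichment_2d(np.asarray(x, float), np.asarray(y, float), mem)

    def test_extreme_ranks_score_one(self, rng):
        x = np.arange(20, dtype=float)
        members = x >= 15  # the m largest values
        res = self._run(x, rng.random(20), members)
        assert res.s_var.iloc[0] == pytest.approx(1.0)

    def test_symmetric_ranks_score_zero(self, rng):
        # members at the extreme low and high ranks balance out
        x = np.arange(12, dtype=float)
        members = np.zeros(12, bool)
        members[[0, 11]] = True
        res = self._run(x, rng.random(12), members)
        assert res.s_var.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_derived_formula_value(self, rng):
        # n = 10, m = 3, member x-ranks {2, 5, 9} -> s = -1/21
        x = np.arange(1, 11, dtype=float)
        members = np.zeros(10, bool)
        members[[1, 4, 8]] = True  # ranks 2, 5, 9
        res = self._run(x, rng.random(10), members)
        assert res.s_var.iloc[0] == pytest.approx(-1 / 21)
        assert res.s_var.iloc[0] == pytest.approx(rank_score_oracle(x, members))

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        members = rng.random(80) < 0.3
        a = self._run(x, y, members)
        b = self._run(np.exp(x), y**3 + 5 * y, members)
        assert a.s_var.iloc[0] == pytest.approx(b.s_var.iloc[0])
        assert a.s_dis.iloc[0] == pytest.approx(b.s_dis.iloc[0])
        assert a.p.iloc[0] == pytest.approx(b.p.iloc[0], rel=1e-9)

    def test_degenerate_membership_skipped(self, rng):
        x, y = rng.random(12), rng.random(12)
        mem = pd.DataFrame({"none": np.zeros(12, bool), "all": np.ones(12, bool),
                            "ok": np.arange(12) < 3})
        with pytest.warns(UserWarning):
            res = enrichment_2d(x, y, mem)
        assert list(res.name) == ["ok"]

    def test_score_bounds_property(self, rng):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        for _ in range(20):
            members = rng.random(60) < rng.uniform(0.05, 0.9)
            if not 0 < members.sum() < 60:
                continue
            res = self._run(x, y, members)
            assert -1 <= res.s_var.iloc[0] <= 1
            assert -1 <= res.s_dis.iloc[0] <= 1

    def test_planted_shift_detected(self, rng):
        n, m = 1000, 100
        members = np.zeros(n, bool)
        members[:m] = True
        x = rng.standard_normal(n)
        x[:m] += 1.0
        res = self._run(x, rng.standard_normal(n), members)
        assert res.s_var.iloc[0] > 0
        assert res.q.iloc[0] < 0.01

    def test_too_few_sites_rejected(self, rng):
        with pytest.raises(ValueError):
            self._run(np.arange(4), np.arange(4), np.array([1, 0, 0, 1], bool))


class TestExcludeMotifSites:
    def _windowed(self, windows):
        df = pd.DataFrame({"protein_id": "P1", "position": np.arange(1, len(windows) + 1),
                           "residue": "S", "window": windows})
        return df

    def test_no_match_is_identity(self):
        t = self._windowed(["AAAAAASAAAAAA"] * 3)
        out = exclude_motif_sites(t, [parse_motif("CDK\tpS/pT-P")])
        assert len(out) == 3

    def test_all_match_empty_with_warning(self, caplog):
        import logging

        t = self._windowed(["AAAAAASPAAAAA"] * 3)
        with caplog.at_level(logging.WARNING):
            out = exclude_motif_sites(t, [parse_motif("CDK\tpS/pT-P")])
        assert out.empty
        assert "every site" in caplog.text

    def test_contrast_source_simulation(self, rng):
        """When the ordered/disordered variability contrast is carried entirely
        by proline-directed sites, excluding them removes it; when the contrast
        is planted independently, it persists."""
        from phosvar import stats_core

        n = 400
        def build(contrast_via_motif):
            windows, var, cat = [], [], []
            for i in range(n):
                disordered = i < n // 2
                # carried arm: 70% of disordered sites are proline-directed
                # and only those carry the elevated variability
                has_p = (disordered and i % 10 < 7) if contrast_via_motif else (i % 2 == 0)
                windows.append("AAAAAAS" + ("P" if has_p else "A") + "AAAAA")
                base = 1.5
                if contrast_via_motif:
                    bump = 1.0 if has_p else 0.0
                else:
                    bump = 1.0 if disordered else 0.0
                var.append(base + bump + 0.1 * rng.standard_normal())
                cat.append("DISORDERED" if disordered else "ORDERED")
            df = self._windowed(windows)
            df["variability"] = var
            df["category2"] = cat
            return df

        motif = [parse_motif("CDK\tpS/pT-P")]

        def contrast(df):
            lo = df.loc[df.category2 == "ORDERED", "variability"]
            hi = df.loc[df.category2 == "DISORDERED", "variability"]
            return hi.median() - lo.median()

        carried = build(True)
        before = contrast(carried)
        after = contrast(exclude_motif_sites(carried, motif))
        assert before > 0.5 and abs(after) < 0.2  # contrast collapses

        independent = build(False)
        after_ind = contrast(exclude_motif_sites(independent, motif))
        assert after_ind > 0.5  # contrast persists


def test_annotate_motifs_on_default_dataset(classified_default, default_dataset):
    motifs = [parse_motif(f"{n}\t{p}") for n, p in default_dataset.motifs]
    mem = annotate_motifs(classified_default, motifs)
    # planted CDK-like members are predominantly disordered
    frac_dis = (
        classified_default.loc[mem["CDK_like"].to_numpy(), "category2"] == "DISORDERED"
    ).mean()
    assert frac_dis > 0.93
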