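"""Envelope assembly from peak tables and suspect matching."""

import random

import pandas as pd
import pytest

from phytoscreen.chem import parse_formula
from phytoscreen.isotopes import isotope_pattern, pattern_to_envelope
from phytoscreen.screening import (assemble_envelopes, match_suspects,
                                   presence_table, read_peak_table)
from phytoscreen.transforms import builtin_rules, enumerate_candidates


def _peaks(rows, sample_id="root_r1", compartment="root", replicate=1):
    return pd.DataFrame(
        [{"mz": mz, "rt_min": rt, "area": area, "sample_id": sample_id,
          "compartment": compartment, "replicate": replicate}
         for mz, rt, area in rows]
    )


def _synthetic_feature(formula, mz_shift_ppm=0.0, rt=5.0, base_area=1e6,
                       sample_id="root_r1", compartment="root", replicate=1):
    """Peak rows for a compound's full theoretical envelope."""
    from phytoscreen.chem import PROTON_MASS

    dist = isotope_pattern(parse_formula(formula), prune=1e-3)
    amax = max(dist.abundances)
    rows = [
        ((m + PROTON_MASS) * (1 + mz_shift_ppm * 1e-6), rt, base_area * a / amax)
        for m, a in dist.entries
    ]
    return _peaks(rows, sample_id, compartment, replicate)


class TestAssembleEnvelopes:
    def test_dichloro_triplet_groups_into_one_feature(self):
        peaks = _peaks([(306.0823, 5.00, 1e6),
                        (308.0794, 5.00, 0.64e6),
                        (310.0765, 5.01, 0.10e6)])
        features = assemble_envelopes(peaks)
        assert len(features) == 1
        f = features[0]
        assert f.mz == 306.0823
        assert f.envelope.intensity == pytest.approx((1.0, 0.64, 0.10))

    def test_single_peak_becomes_singleton(self):
        features = assemble_envelopes(_peaks([(400.123, 3.0, 5e4)]))
        assert len(features) == 1
        assert features[0].envelope.intensity == (1.0,)

    def test_separated_retention_times_stay_apart(self):
        peaks = _peaks([(306.0823, 5.0, 1e6), (308.0794, 5.5, 0.64e6)])
        assert len(assemble_envelopes(peaks)) == 2

    def test_non_isotopic_spacing_not_grouped(self):
        peaks = _peaks([(306.0823, 5.0, 1e6), (306.5823, 5.0, 0.6e6)])
        assert len(assemble_envelopes(peaks)) == 2

    def test_empty_input(self):
        assert assemble_envelopes(pd.DataFrame(
            columns=["mz", "rt_min", "area", "sample_id"])) == []

    def test_lowest_mz_is_monoisotopic(self):
        # A+1 larger than A still anchors on the lowest m/z
        peaks = _peaks([(500.0, 2.0, 1e5), (501.0034, 2.0, 2e5)])
        f = assemble_envelopes(peaks)[0]
        assert f.mz == 500.0


@pytest.fixture(scope="module")
def candidates():
    out = []
    for parent in ("STR", "CLP", "TZN"):
        out.extend(enumerate_candidates(parent, builtin_rules(), max_depth=3))
    return out


class TestMatchSuspects:
    def test_oh_str_matches_with_small_ppm(self, candidates):
        features = assemble_envelopes(
            _synthetic_feature("C17H17Cl2NO", mz_shift_ppm=0.6, rt=6.7))
        matches = match_suspects(features, candidates)
        names = {m.candidate.formula.hill() for m in matches}
        assert names == {"C17H17Cl2NO"}
        assert matches[0].ppm == pytest.approx(0.6, abs=0.05)

    def test_distinct_rts_reported_as_isomers(self, candidates):
        peaks = pd.concat([
            _synthetic_feature("C17H17Cl2NO", rt=6.7),
            _synthetic_feature("C17H17Cl2NO", rt=8.2),
        ])
        matches = match_suspects(assemble_envelopes(peaks), candidates)
        assert [m.isomer_index for m in matches] == [1, 2]
        assert matches[0].rt < matches[1].rt

    def test_far_mass_not_matched(self, candidates):
        features = assemble_envelopes(_peaks([(322.20, 6.7, 1e6)]))
        assert match_suspects(features, candidates) == []

    def test_singleton_fails_envelope_gate(self, candidates):
        # right mass, but no isotope envelope: rejected at score 0.7
        features = assemble_envelopes(_peaks([(322.0762, 6.7, 1e6)]))
        assert match_suspects(features, candidates) == []

    def test_all_matches_within_tolerance_by_construction(self, candidates):
        peaks = pd.concat([
            _synthetic_feature("C17H17Cl2N", mz_shift_ppm=3.9, rt=10.2),
            _synthetic_feature("C19H23ClN2", mz_shift_ppm=4.8, rt=10.7),
        ])
        matches = match_suspects(assemble_envelopes(peaks), candidates,
                                 ppm_tol=5.0)
        assert matches
        assert all(abs(m.ppm) <= 5.0 for m in matches)
        assert all(m.envelope_score >= 0.7 for m in matches)

    def test_input_order_invariance(self, candidates):
        peaks = pd.concat([
            _synthetic_feature("C17H17Cl2N", rt=10.2),
            _synthetic_feature("C19H22ClN5O", rt=5.5),
        ])
        features = assemble_envelopes(peaks)
        reference = match_suspects(features, candidates)
        rng = random.Random(1)
        shuffled_f = list(features)
        shuffled_c = list(candidates)
        rng.shuffle(shuffled_f)
        rng.shuffle(shuffled_c)
        again = match_suspects(shuffled_f, shuffled_c)
        key = lambda m: (m.candidate.formula.hill(), m.feature.mz, m.rt)
        assert sorted(map(key, reference)) == sorted(map(key, again))


class TestPresenceTable:
    def test_replicates_kept_separate(self):
        cands = enumerate_candidates("STR", builtin_rules(), max_depth=0)
        peaks = pd.concat([
            _synthetic_feature("C17H17Cl2N", rt=10.2, base_area=a,
                               sample_id=f"root_r{i}", replicate=i)
            for i, a in enumerate([1e6, 1.2e6, 0.9e6], start=1)
        ])
        matches = match_suspects(assemble_envelopes(peaks), cands)
        table = presence_table(matches)
        root = table[table["compartment"] == "root"]
        assert len(root) == 3
        assert sorted(root["replicate"]) == [1, 2, 3]
        assert root["area"].tolist() == pytest.approx([1e6, 1.2e6, 0.9e6])

    def test_empty_matches_empty_table(self):
        assert presence_table([]).empty


def test_read_peak_table_requires_core_columns(tmp_path):
    p = tmp_path / "peaks.csv"
    p.write_text("mz,rt_min\n100,1\n")
    with pytest.raises(ValueError, match="area"):
        read_peak_table(p)
    p2 = tmp_path / "peaks2.csv"
    p2.write_text("mz,rt_min,area\n100,1,10\n")
    df = read_peak_table(p2)
    assert df["sample_id"].iloc[0] == "peaks2"
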