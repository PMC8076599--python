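"""Spectral scoring, qualifier validation and the three-criterion decision."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from oocyteflux.identify import (IdentificationParams, forward_score,
                                 identify_peak, map_conversion_products,
                                 qualifier_check, reverse_score)

PARAMS = IdentificationParams()


def oracle_score(query, library, support_library_only, scale):
    """Brute-force re-implementation of the weighted cosine (plain Python)."""
    q = {mz: i for mz, i in query if mz not in (73, 147) and i > 0}
    l = {mz: i for mz, i in library if mz not in (73, 147) and i > 0}
    if not q or not l:
        return 0.0
    wq = {mz: math.sqrt(i) * mz for mz, i in q.items()}
    wl = {mz: math.sqrt(i) * mz for mz, i in l.items()}
    support = set(l) if support_library_only else set(q) | set(l)
    dot = sum(wq.get(mz, 0.0) * wl.get(mz, 0.0) for mz in support)
    nq = math.sqrt(sum(wq.get(mz, 0.0) ** 2 for mz in support))
    nl = math.sqrt(sum(wl.get(mz, 0.0) ** 2 for mz in support))
    if nq == 0 or nl == 0:
        return 0.0
    return scale * dot / (nq * nl)


def random_spectrum(rng, n=8):
    mzs = rng.choice(np.arange(50, 550), size=n, replace=False)
    return [(int(mz), float(i)) for mz, i in
            zip(mzs, rng.uniform(0.05, 1.0, size=n))]


class TestScores:
    def test_self_match_identities(self, by_name):
        spec = by_name["Valine"].spectrum
        assert forward_score(spec, spec) == pytest.approx(1000.0, abs=1e-9)
        assert reverse_score(spec, spec) == pytest.approx(999.0, abs=1e-9)

    def test_disjoint_spectra_score_zero(self):
        a = [(100, 1.0), (200, 0.5)]
        b = [(150, 1.0), (250, 0.5)]
        assert forward_score(a, b) == 0.0

    def test_reverse_ignores_contaminant_ions(self, by_name):
        lib = by_name["Valine"].spectrum
        query = list(lib) + [(501, 0.8), (502, 0.6)]
        assert reverse_score(query, lib) == pytest.approx(999.0, abs=1e-9)
        assert forward_score(query, lib) < 1000.0

    def test_scores_match_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            q, l = random_spectrum(rng), random_spectrum(rng)
            # overlap some ions so scores are non-trivial
            q[:3] = l[:3]
            assert forward_score(q, l) == pytest.approx(
                oracle_score(q, l, False, 1000.0), rel=1e-9, abs=1e-9)
            assert reverse_score(q, l) == pytest.approx(
                oracle_score(q, l, True, 999.0), rel=1e-9, abs=1e-9)

    def test_excluded_tms_ions_carry_no_information(self):
        only_tms = [(73, 1.0), (147, 0.5)]
        assert forward_score(only_tms, [(100, 1.0)]) == 0.0
        assert reverse_score(only_tms, [(100, 1.0)]) == 0.0


class TestQualifierCheck:
    def _query(self, rec, errors):
        """Query spectrum whose qualifier ratios are off by given factors."""
        lib = {mz: i for mz, i in rec.spectrum if mz not in (73, 147)}
        quals = sorted((mz for mz in lib if mz != rec.quantifier_mz),
                       key=lambda mz: -lib[mz])
        out = {rec.quantifier_mz: 1.0}
        for mz, err in zip(quals, errors):
            out[mz] = lib[mz] * (1.0 + err)
        return list(out.items())

    def test_exact_ratios_pass_with_zero_errors(self, by_name):
        rec = by_name["Valine"]
        ok, errors = qualifier_check(list(rec.spectrum), rec)
        assert ok
        assert all(e == pytest.approx(0.0, abs=1e-12)
                   for e in errors.values())

    def test_mean_error_rule_fails_despite_two_correct_ions(self, by_name):
        rec = by_name["Valine"]
        ok, errors = qualifier_check(
            self._query(rec, [0.25, -0.25, 2.0, 2.0]), rec)
        # 2 ions within 30%, but mean error (25+25+200+200)/4 > 70%
        assert not ok

    def test_two_correct_ions_and_low_mean_pass(self, by_name):
        rec = by_name["Valine"]
        ok, errors = qualifier_check(
            self._query(rec, [0.29, -0.29, 0.5, 0.5]), rec)
        assert ok  # 2 correct, mean 39% <= 70%

    def test_missing_quantifier_fails_with_reason(self, by_name):
        rec = by_name["Valine"]
        query = [(mz, i) for mz, i in rec.spectrum
                 if mz != rec.quantifier_mz]
        ok, info = qualifier_check(query, rec)
        assert not ok and "quantifier" in info["reason"]


def _peak(spectrum, ri, height=5000.0, symmetry=0.95):
    return SimpleNamespace(spectrum=tuple(spectrum), assigned_ri=ri,
                           height=height, symmetry=symmetry, area=1e5)


class TestIdentifyPeak:
    def test_clean_valine_with_standards_reaches_criterion_2(self, library,
                                                             by_name):
        rec = by_name["Valine"]
        ident = identify_peak(_peak(rec.spectrum, rec.retention_index),
                              library, PARAMS,
                              standard_confirmed_names={"Valine"})
        assert ident.name == "Valine" and ident.criterion == "2"
        assert ident.standard_confirmed

    def test_without_standard_confirmation_stays_criterion_1(self, library,
                                                             by_name):
        rec = by_name["Valine"]
        ident = identify_peak(_peak(rec.spectrum, rec.retention_index),
                              library, PARAMS)
        assert ident.criterion == "1"

    def test_ri_offset_beyond_3_falls_back_to_criterion_3(self, library,
                                                          by_name):
        rec = by_name["Valine"]
        ident = identify_peak(_peak(rec.spectrum, rec.retention_index + 3.5),
                              library, PARAMS)
        assert ident.name == "Valine"
        assert ident.criterion == "3"   # good spectrum, wrong RI

    def test_low_abundance_fails_criterion_1(self, library, by_name):
        rec = by_name["Valine"]
        ident = identify_peak(
            _peak(rec.spectrum, rec.retention_index, height=400.0),
            library, PARAMS)
        assert ident.criterion != "1"

    def test_pure_tms_reagent_spectrum_is_unidentified(self, library,
                                                       by_name):
        ri = by_name["Valine"].retention_index
        ident = identify_peak(_peak([(73, 1.0), (147, 0.6)], ri),
                              library, PARAMS)
        assert ident.criterion == "unidentified" and ident.name is None

    def test_far_ri_is_unidentified(self, library):
        ident = identify_peak(_peak([(100, 1.0), (200, 0.5)], 3000.0),
                              library, PARAMS)
        assert ident.criterion == "unidentified"

    def test_criterion_tiers_are_mutually_exclusive(self, library, by_name):
        rng = np.random.default_rng(5)
        tiers = set()
        for rec in library:
            noisy = [(mz, max(i * (1 + rng.normal(0, 0.1)), 1e-6))
                     for mz, i in rec.spectrum]
            ident = identify_peak(
                _peak(noisy, rec.retention_index + rng.normal(0, 1.0)),
                library, PARAMS, standard_confirmed_names={rec.name})
            assert ident.criterion in {"1", "2", "3", "unidentified"}
            tiers.add(ident.criterion)
        assert "2" in tiers


class TestConversionProducts:
    def _ident(self, name):
        from oocyteflux.identify import IdentifiedMetabolite
        return IdentifiedMetabolite(peak=None, name=name, criterion="1")

    def test_ornithine_flagged_with_arginine_parent(self):
        out = map_conversion_products([self._ident("Ornithine")])
        assert out[0].is_conversion_product
        assert out[0].conversion_parents == ("Arginine",)

    def test_pyroglutamate_has_two_parents(self):
        out = map_conversion_products([self._ident("Pyroglutamic acid")])
        assert set(out[0].conversion_parents) == {"Glutamic acid",
                                                  "Glutamine"}

    def test_other_metabolites_unchanged(self):
        out = map_conversion_products([self._ident("Valine")])
        assert not out[0].is_conversion_product
        assert out[0].conversion_parents == ()
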