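"""Fold-change / absolute-delta profiling statistics and substrate calls."""

import numpy as np
import pandas as pd
import pytest

from oocyteflux.matrix import AbundanceMatrix
from oocyteflux.profiles import (absolute_delta,
                                 compute_profile, exchanger_profile,
                                 fold_change, paired_test,
                                 write_heatmap_tables)
from oocyteflux.simulate import design_for, simulate_abundance_matrix


def make_matrix(rows, tx, ui, labels=("t0", "t4"), n_reps=3, ribitol=None):
    """Matrix with per-(label, replicate) transporter/uninjected columns.

    ``tx``/``ui`` map metabolite -> {label: value or per-replicate list}.
    """
    cols, meta = {}, []
    order = 0
    for rep in range(n_reps):
        for lab in labels:
            for role, source in (("transporter", tx), ("uninjected", ui)):
                order += 1
                sid = f"{role}_r{rep}_{lab}"
                vals = {}
                for met in rows:
                    v = source[met][lab]
                    vals[met] = v[rep] if isinstance(v, (list, tuple)) else v
                cols[sid] = vals
                meta.append({"sample_id": sid, "role": role,
                             "replicate": rep, "timepoint": lab,
                             "injection_order": order, "transporter": "X",
                             "ribitol_height": 1000.0})
    m = AbundanceMatrix(values=pd.DataFrame(cols),
                        samples=pd.DataFrame(meta).set_index("sample_id"))
    if ribitol is not None:
        m.negative_control = pd.Series(
            {sid: ribitol for sid in m.values.columns})
    return m


class TestFoldChangeAndDelta:
    def test_identical_groups_give_fc_one_and_delta_zero(self):
        flat = {"t0": 800.0, "t4": 800.0}
        m = make_matrix(["Met"], {"Met": flat}, {"Met": flat})
        assert (fold_change(m) == 1.0).all().all()
        assert (absolute_delta(m) == 0.0).all().all()

    def test_planted_threefold_accumulation(self):
        m = make_matrix(["Leu"], {"Leu": {"t0": 900.0, "t4": 2700.0}},
                        {"Leu": {"t0": 900.0, "t4": 900.0}})
        fc = fold_change(m)
        assert fc.loc["Leu", "t4"] == pytest.approx(3.0)
        assert fc.loc["Leu", "t0"] == pytest.approx(1.0)

    def test_planted_thousand_unit_shift(self):
        m = make_matrix(["Asp"], {"Asp": {"t0": 5000.0, "t4": 6000.0}},
                        {"Asp": {"t0": 5000.0, "t4": 5000.0}})
        assert absolute_delta(m).loc["Asp", "t4"] == pytest.approx(1000.0)

    def test_missing_controls_is_hard_failure(self):
        m = make_matrix(["Met"], {"Met": {"t0": 1.0, "t4": 1.0}},
                        {"Met": {"t0": 1.0, "t4": 1.0}})
        keep = m.samples.index[m.samples["role"] == "transporter"]
        m2 = m.drop_samples([c for c in m.values.columns if c not in keep])
        with pytest.raises(ValueError, match="un-injected"):
            fold_change(m2)


class TestPairedTest:
    def test_identical_paired_values_give_p_one(self):
        m = make_matrix(["Met"], {"Met": {"t0": 700.0, "t4": 700.0}},
                        {"Met": {"t0": 700.0, "t4": 700.0}})
        assert paired_test(m, "Met") == 1.0

    def test_single_pair_is_undefined(self):
        m = make_matrix(["Met"], {"Met": {"t0": 700.0, "t4": 900.0}},
                        {"Met": {"t0": 700.0, "t4": 700.0}}, n_reps=1)
        assert np.isnan(paired_test(m, "Met"))

    def test_large_consistent_shift_is_significant(self):
        tx = {"Met": {"t0": [1000.0, 1010.0, 990.0],
                      "t4": [1500.0, 1515.0, 1490.0]}}
        ui = {"Met": {"t0": 1000.0, "t4": 1000.0}}
        m = make_matrix(["Met"], tx, ui)
        assert paired_test(m, "Met") < 0.05

    def test_null_rejection_rate_controlled(self):
        """Type-I quick check: ~5% at alpha 0.05 over simulated null
        batches (the full >= 500-batch calibration runs in acceptance)."""
        rej = tot = 0
        for seed in range(40):
            d = design_for("uninjected", seed=seed, drift_enabled=False)
            prof = compute_profile(simulate_abundance_matrix(d))
            p = prof.p_values.dropna()
            rej += int((p < 0.05).sum())
            tot += len(p)
        assert 0.02 <= rej / tot <= 0.08


class TestCalls:
    def test_flat_matrix_all_unchanged(self):
        flat = {"t0": 900.0, "t4": 900.0}
        m = make_matrix(["Met", "Leu"], {"Met": flat, "Leu": flat},
                        {"Met": flat, "Leu": flat}, ribitol=1000.0)
        prof = compute_profile(m)
        assert (prof.calls == "unchanged").all()

    def test_ribitol_excluded_from_calls(self):
        d = design_for("SNAT2-like", seed=1)
        prof = compute_profile(simulate_abundance_matrix(d))
        assert "Ribitol" not in prof.calls.index
        assert "Ribitol" in prof.fold_change.index

    def test_snat2_accumulates_leucine_and_proline_snat1_does_not(self):
        calls = {}
        for name in ("SNAT2-like", "SNAT1-like"):
            d = design_for(name, seed=1)
            calls[name] = compute_profile(simulate_abundance_matrix(d)).calls
        assert calls["SNAT2-like"]["Leucine"] == "accumulated"
        assert calls["SNAT2-like"]["Proline"] == "accumulated"
        assert calls["SNAT1-like"]["Leucine"] == "unchanged"
        assert calls["SNAT1-like"]["Proline"] == "unchanged"

    def test_not_significant_is_always_unchanged(self):
        d = design_for("B0AT1-like", seed=2)
        prof = compute_profile(simulate_abundance_matrix(d))
        for met in prof.calls.index:
            if not prof.significant[met]:
                assert prof.calls[met] == "unchanged"

    def test_fc_and_delta_agree_in_sign_when_both_detected(self):
        d = design_for("SNAT2-like", seed=3)
        prof = compute_profile(simulate_abundance_matrix(d))
        end = prof.labels[-1]
        for met in prof.calls.index:
            if prof.fc_detected[met] and prof.delta_detected[met]:
                assert (prof.fold_change.loc[met, end] > 1) == \
                    (prof.absolute_delta.loc[met, end] > 0)


class TestExchangerProfile:
    def test_missing_phase_column_is_hard_failure(self):
        flat = {"t0": 900.0, "t4": 900.0}
        m = make_matrix(["Met"], {"Met": flat}, {"Met": flat})
        with pytest.raises(ValueError, match="phase"):
            exchanger_profile(m)

    def test_null_design_has_no_phase_signs(self):
        flat = {"baseline": 900.0, "preloaded": 900.0, "medium": 900.0}
        m = make_matrix(["Met"], {"Met": flat}, {"Met": flat},
                        labels=("baseline", "preloaded", "medium"))
        prof = exchanger_profile(m)
        assert (prof.phase_signs == "").all().all()

    def test_lat1_preload_and_efflux_signs(self):
        """Ile preload: Ile +, aromatics -; medium phase: Ile -, Leu/Phe/Trp +."""
        d = design_for("LAT1-like", seed=1,
                       preload=("Isoleucine", 10000.0, 6.0))
        prof = exchanger_profile(simulate_abundance_matrix(d))
        signs = prof.phase_signs
        assert signs.loc["Isoleucine", "preload"] == "+"
        for met in ("Tryptophan", "Tyrosine", "Phenylalanine"):
            assert signs.loc[met, "preload"] == "-"
        assert signs.loc["Isoleucine", "medium"] == "-"
        for met in ("Leucine", "Phenylalanine", "Tryptophan"):
            assert signs.loc[met, "medium"] == "+"

    def test_antiport_pool_deltas_conserve_over_phases(self, transporters):
        """At the amount level with zero noise, the summed change of the
        substrate set over both phases is zero for a pure antiporter."""
        from oocyteflux.simulate import simulate_pools
        model = transporters["LAT1-like"]
        d = design_for("LAT1-like", seed=1, drift_enabled=False,
                       preload=("Isoleucine", 10000.0, 6.0))
        state = simulate_pools(d, model)[0]
        subs = [s for s in model.substrates if s in state.amounts.index]
        total_change = (state.at("medium")[subs] - state.at("baseline")[subs]).sum()
        assert total_change == pytest.approx(0.0, abs=1e-6 * 1096)


class TestHeatmapTables:
    def test_ribitol_and_conversion_rows_present(self, snat2_result):
        *_, result = snat2_result
        fc_tsv, d_tsv = write_heatmap_tables(result.profile)
        assert "Ribitol" in fc_tsv
        assert "Ornithine" in fc_tsv and "Pyroglutamic acid" in fc_tsv
        assert "Ornithine" in d_tsv

    def test_significance_marks_match_p_values(self, snat2_result):
        *_, result = snat2_result
        fc_tsv, _ = write_heatmap_tables(result.profile)
        lines = {ln.split("\t")[0]: ln for ln in fc_tsv.splitlines()[1:]}
        for met, p in result.profile.p_values.items():
            if met in lines and p == p:
                assert ("*" in lines[met]) == (p < 0.05)

    def test_empty_profile_gives_headers_only(self):
        flat = {"t0": 900.0, "t4": 900.0}
        m = make_matrix(["Met"], {"Met": flat}, {"Met": flat})
        prof = compute_profile(m.drop_metabolites(["Met"]))
        fc_tsv, d_tsv = write_heatmap_tables(prof)
        assert fc_tsv.splitlines()[0].startswith("metabolite")
        assert len(fc_tsv.splitlines()) == 1
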