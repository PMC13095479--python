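"""CSV dialect readers, the three-file export and its exact round trip."""

import os

import pytest

from rlcfit import (
    CurveReadError,
    SimulationSpec,
    emit_instrument_csv,
    fit_model,
    generate_curve,
    read_dual_pam,
    read_junior_pam,
    read_parameters_csv,
    read_universal,
    write_model_results,
)
from rlcfit.synthetic_data import REFERENCE_PARAMS

DIALECT_READERS = {
    "universal": lambda p: read_universal(p),
    "dual_pam": lambda p: read_dual_pam(p, keep_recovery=True),
    "junior_pam": lambda p: read_junior_pam(p, keep_recovery=True),
}


class TestReadUniversal:
    def test_etr_arithmetic(self, tmp_path):
        f = tmp_path / "u.csv"
        f.write_text("PAR,Y(II)\n0,0.7\n100,0.6\n")
        curve = read_universal(f, etr_factor=0.84, p_ratio=0.5)
        assert [s.etr for s in curve.steps] == pytest.approx([0.0, 25.2])

    def test_header_only_is_empty_curve(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("PAR,Y(II)\n")
        with pytest.raises(CurveReadError, match="empty curve"):
            read_universal(f)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_universal(tmp_path / "nope.csv")

    def test_missing_column_named_in_error(self, tmp_path):
        f = tmp_path / "u.csv"
        f.write_text("PAR,Fv\n100,0.6\n")
        with pytest.raises(CurveReadError, match=r"Y\(II\)"):
            read_universal(f)

    def test_non_numeric_row_numbered(self, tmp_path):
        f = tmp_path / "u.csv"
        f.write_text("PAR,Y(II)\n0,0.7\nabc,0.6\n")
        with pytest.raises(CurveReadError, match="row 2"):
            read_universal(f)

    def test_yield_outside_unit_interval_rejected(self, tmp_path):
        f = tmp_path / "u.csv"
        f.write_text("PAR,Y(II)\n100,1.7\n")
        with pytest.raises(CurveReadError, match="outside"):
            read_universal(f)

    def test_column_map(self, tmp_path):
        f = tmp_path / "u.csv"
        f.write_text("irradiance,phi2\n100,0.6\n")
        curve = read_universal(f, column_map={"irradiance": "PAR", "phi2": "Y(II)"})
        assert curve.steps[0].etr == pytest.approx(25.2)

    def test_bom_tolerated(self, tmp_path):
        f = tmp_path / "u.csv"
        f.write_bytes(b"\xef\xbb\xbfPAR,Y(II)\n100,0.6\n")
        assert read_universal(f).steps[0].etr == pytest.approx(25.2)


class TestInstrumentDialects:
    def _emit(self, tmp_path, dialect, n_recovery=3, **kwargs):
        spec = SimulationSpec(model="platt", params=REFERENCE_PARAMS["platt"],
                              seed=7, n_recovery=n_recovery, **kwargs)
        curve, _ = generate_curve(spec)
        path = tmp_path / f"{dialect}.csv"
        emit_instrument_csv(curve, dialect, path)
        return curve, path

    def test_dual_pam_recovery_excluded_by_default(self, tmp_path):
        _, path = self._emit(tmp_path, "dual_pam")
        curve = read_dual_pam(path)
        assert len(curve.steps) == 12
        assert not any(s.is_recovery for s in curve.steps)

    def test_dual_pam_keep_recovery_flags_rows(self, tmp_path):
        _, path = self._emit(tmp_path, "dual_pam")
        curve = read_dual_pam(path, keep_recovery=True)
        assert len(curve.steps) == 15
        assert sum(s.is_recovery for s in curve.steps) == 3
        assert len(curve.light_steps) == 12

    def test_junior_pam_decimal_comma(self, tmp_path):
        gen, path = self._emit(tmp_path, "junior_pam", n_recovery=0)
        assert "," in path.read_text().splitlines()[3].split(";")[3]
        curve = read_junior_pam(path)
        for a, b in zip(curve.steps, gen.steps):
            assert a.quantum_yield == pytest.approx(b.quantum_yield, rel=1e-9)

    def test_junior_pam_schedule_break_recovery(self, tmp_path):
        _, path = self._emit(tmp_path, "junior_pam")
        assert len(read_junior_pam(path).steps) == 12
        kept = read_junior_pam(path, keep_recovery=True)
        assert sum(s.is_recovery for s in kept.steps) == 3

    def test_dual_file_in_junior_reader_is_dialect_error(self, tmp_path):
        _, path = self._emit(tmp_path, "dual_pam")
        with pytest.raises(CurveReadError, match="junior_pam"):
            read_junior_pam(path)

    def test_terminal_zero_yield_step_retained(self, tmp_path):
        _, path = self._emit(tmp_path, "dual_pam", n_recovery=0,
                             terminal_zero_yield=True)
        curve = read_dual_pam(path)
        last = curve.steps[-1]
        assert last.quantum_yield == 0.0 and last.etr == 0.0
        assert len(curve.steps) == 12
        fit = fit_model(curve, "platt")  # fitting must not choke on it
        assert fit.converged

    @pytest.mark.parametrize("dialect", sorted(DIALECT_READERS))
    def test_emit_read_emit_byte_stable(self, dialect, tmp_path):
        gen, path = self._emit(tmp_path, dialect, n_recovery=2)
        curve = DIALECT_READERS[dialect](path)
        again = tmp_path / "again.csv"
        emit_instrument_csv(curve, dialect, again)
        assert again.read_text() == path.read_text()
        for a, b in zip(curve.steps, gen.steps):
            assert a.par == pytest.approx(b.par, rel=1e-9)
            assert a.quantum_yield == pytest.approx(b.quantum_yield, rel=1e-9)
            assert a.etr == pytest.approx(b.etr, rel=1e-9)


class TestThreeFileExport:
    @pytest.fixture
    def fitted(self, noise_free_curve):
        curve, _ = noise_free_curve("eilers_peeters")
        return curve, fit_model(curve, "eilers_peeters")

    def test_exactly_three_files(self, fitted, tmp_path):
        curve, fit = fitted
        paths = write_model_results(fit, curve, tmp_path, "m1")
        assert len(paths) == 3
        assert all(os.path.exists(p) for p in paths)
        assert sorted(os.path.basename(p) for p in paths) == [
            "m1_parameters.csv", "m1_regression.csv", "m1_table.csv"]

    def test_eilers_beta_is_na(self, fitted, tmp_path):
        curve, fit = fitted
        _, _, p_par = write_model_results(fit, curve, tmp_path, "m1")
        derived, values = read_parameters_csv(p_par)
        assert derived.beta is None
        assert values["beta"] is None

    def test_readback_reproduces_derived_exactly(self, fitted, tmp_path):
        curve, fit = fitted
        _, _, p_par = write_model_results(fit, curve, tmp_path, "m1")
        derived, values = read_parameters_csv(p_par)
        assert derived == fit.derived  # bitwise: 17-digit round trip
        assert values["etr_factor"] == curve.etr_factor
        assert values["p_ratio"] == curve.p_ratio
        assert values["residual_sum_of_squares"] == fit.metrics.rss

    def test_non_converged_fit_refused(self, fitted, tmp_path):
        import dataclasses
        curve, fit = fitted
        bad = dataclasses.replace(fit, converged=False)
        with pytest.raises(ValueError):
            write_model_results(bad, curve, tmp_path, "m2")
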