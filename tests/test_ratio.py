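"""Mixture-fraction estimation: closed form, oracle equivalence, pipeline."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from sangermix import (
    Chromatogram,
    DegenerateContrastError,
    DivergenceError,
    RunConfig,
    SimSpec,
    ValidationError,
    divergent_pair,
    make_warp_knots,
    quantify,
    simulate_mixture,
)
from sangermix.align import AlignmentColumn
from sangermix.ratio import _solve, informative_columns


def _col(m_index, m_primary, m_secondary, p1, p2):
    return AlignmentColumn(m_index=m_index, p1_index=m_index, p2_index=m_index,
                           m_primary=m_primary, m_secondary=m_secondary,
                           p1_base=p1, p2_base=p2, score=0.0)


class TestInformativeColumns:
    def test_window_and_divergence_filter(self):
        cols = [
            _col(100, "G", "T", "G", "T"),   # informative
            _col(700, "G", "T", "G", "T"),   # outside window
            _col(200, "G", None, "G", "G"),  # refs identical
            _col(300, "A", "C", "G", "T"),   # mismatch
            _col(400, "G", None, "G", "T"),  # single peak matching one ref
        ]
        kept, n_mismatch = informative_columns(cols, window=(20, 600))
        assert [c.m_index for c in kept] == [100, 400]
        assert n_mismatch == 1

    def test_half_matching_two_peak_column_ignored(self):
        # one of two peaks matches: neither informative nor a mismatch
        cols = [_col(100, "G", "T", "G", "T"), _col(150, "G", "A", "G", "T")]
        kept, n_mismatch = informative_columns(cols, window=(20, 600))
        assert len(kept) == 1 and n_mismatch == 0

    def test_call_offset_shifts_window(self):
        cols = [_col(5, "G", "T", "G", "T")]
        kept, _ = informative_columns(cols, window=(20, 600), call_offset=20)
        assert len(kept) == 1
        with pytest.raises(DivergenceError):
            informative_columns(cols, window=(20, 600), call_offset=700)

    def test_no_divergence_errors(self):
        with pytest.raises(DivergenceError):
            informative_columns([_col(100, "G", None, "G", "G")], window=(20, 600))


class TestClosedForm:
    def test_pure_limits(self, rng):
        g1 = rng.uniform(1, 100, 50)
        g2 = rng.uniform(1, 100, 50)
        omega, resid, clamped = _solve(g1.copy(), g1, g2)
        assert omega == 1.0 and resid == pytest.approx(0.0, abs=1e-18)
        omega, resid, _ = _solve(g2.copy(), g1, g2)
        assert omega == 0.0 and resid == pytest.approx(0.0, abs=1e-18)

    def test_symmetric_mixture(self, rng):
        g1 = rng.uniform(1, 100, 50)
        g2 = rng.uniform(1, 100, 50)
        omega, _, _ = _solve(0.5 * (g1 + g2), g1, g2)
        assert omega == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_contrast(self, rng):
        g = rng.uniform(1, 100, 20)
        with pytest.raises(DegenerateContrastError):
            _solve(g, g, g)

    def test_matches_numeric_minimizer(self, rng):
        """Closed form equals a grid + bounded-refinement minimizer of the
        least-squares objective on random positive instances (1e-6)."""
        for _ in range(120):
            n = int(rng.integers(10, 60))
            g1 = rng.uniform(0, 1000, n)
            g2 = rng.uniform(0, 1000, n)
            w_true = rng.uniform(-0.3, 1.3)  # sometimes outside [0, 1]
            y = np.clip(w_true * g1 + (1 - w_true) * g2 + rng.normal(0, 20, n), 0, None)

            def objective(w):
                r = y - w * g1 - (1 - w) * g2
                return float(r @ r)

            grid = np.linspace(0, 1, 101)
            w0 = grid[np.argmin([objective(w) for w in grid])]
            lo, hi = max(0.0, w0 - 0.02), min(1.0, w0 + 0.02)
            res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            omega, resid, _ = _solve(y, g1, g2)
            assert omega == pytest.approx(float(res.x), abs=1e-6)
            assert resid == pytest.approx(objective(omega), rel=1e-12)


class TestQuantify:
    def test_exact_recovery_noise_free(self, clean_pair_specs):
        seq1, seq2, spec = clean_pair_specs
        for omega in (0.0, 0.3, 1.0):
            m, r1, r2 = simulate_mixture(seq1, seq2, omega, spec, spec, spec)
            est = quantify(m, r1, r2)
            assert est.omega == pytest.approx(omega, abs=1e-3)
            assert est.residual < 1e-12 * est.n_informative

    def test_mild_warp_recovery(self, rng):
        seq1, seq2 = divergent_pair(300, 25, rng)
        specs = [
            SimSpec(noise_sd=0.0, seed=i,
                    warp_knots=make_warp_knots(rng, 310 * 12, strength=0.05))
            for i in (1, 2, 3)
        ]
        m, r1, r2 = simulate_mixture(seq1, seq2, 0.3, *specs)
        est = quantify(m, r1, r2)
        assert est.omega == pytest.approx(0.3, abs=0.01)

    def test_identical_references_error_names_stage(self, clean_pair_specs):
        seq1, _, spec = clean_pair_specs
        m, r1, r2 = simulate_mixture(seq1, seq1, 0.5, spec, spec, spec)
        with pytest.raises(DivergenceError, match="diverge") as exc:
            quantify(m, r1, r2)
        assert exc.value.stage == "informative_columns"

    def test_provenance_fields(self, clean_triple):
        est = quantify(*clean_triple)
        assert est.n_anchors >= 5
        assert est.n_informative >= 1
        assert est.alignment_scores[0] > 0
        assert est.config["rel_threshold"] == 0.014
        d = est.to_dict()
        assert set(d) >= {"omega", "residual", "n_informative", "n_anchors"}

    def test_per_column_diagnostics_near_global(self, clean_triple):
        est = quantify(*clean_triple)
        vals = np.array([w for _, w in est.per_column])
        assert np.nanmax(np.abs(vals - 0.3)) < 0.01

    def test_scale_invariance(self, clean_triple):
        m, r1, r2 = clean_triple
        est1 = quantify(m, r1, r2)
        m_scaled = Chromatogram({b: 7.3 * a for b, a in m.channels.items()},
                                m.peak_times, m.basecalls, m.sample_id)
        est2 = quantify(m_scaled, r1, r2)
        assert est2.omega == pytest.approx(est1.omega, abs=1e-12)

    def test_monotone_in_true_fraction(self, clean_pair_specs):
        seq1, seq2, spec = clean_pair_specs
        estimates = []
        for omega in np.arange(0, 1.01, 0.1):
            m, r1, r2 = simulate_mixture(seq1, seq2, float(omega), spec, spec, spec)
            estimates.append(quantify(m, r1, r2).omega)
        assert all(b >= a for a, b in zip(estimates, estimates[1:]))

    def test_full_integration_mode(self, clean_triple):
        est = quantify(*clean_triple, config=RunConfig(integration="full"))
        assert est.omega == pytest.approx(0.3, abs=0.01)


class TestRunConfig:
    def test_window_must_sit_inside_trim(self):
        with pytest.raises(ValidationError):
            RunConfig(window=(10, 600))

    def test_from_file_json(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text('{"rel_threshold": 0.02, "window": [30, 500]}')
        cfg = RunConfig.from_file(p)
        assert cfg.rel_threshold == 0.02 and cfg.window == (30, 500)

    def test_from_file_toml(self, tmp_path):
        p = tmp_path / "cfg.toml"
        p.write_text('abs_threshold = 40.0\nmin_anchors = 6\n')
        cfg = RunConfig.from_file(p)
        assert cfg.abs_threshold == 40.0 and cfg.min_anchors == 6

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text('{"not_a_key": 1}')
        with pytest.raises(ValidationError):
            RunConfig.from_file(p)
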