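import numpy as np
import pytest

from srcca.errors import ConfigError, DegenerateInputError, UsageError
from srcca.expression_io import ExpressionMatrix
from srcca.markers import (
    core_signature,
    marker_recovery,
    specificity_contrast,
    subtype_candidates,
    validate_candidate,
)
from srcca.panels import MarkerPanel


def planted_core_matrix(seed=0, n_noise=50, n_cells=40):
    """Four targets sharing one expression pattern + 11 exact co-followers."""
    rng = np.random.default_rng(seed)
    t = rng.normal(10, 3, size=n_cells) ** 2
    rows, names = [], []
    for sym in ("POU4F2", "ISL1", "SNCG", "RBPMS"):
        rows.append(t + rng.normal(0, 1e-9, n_cells))  # same rank pattern
        names.append(sym)
    for i in range(11):
        rows.append(2.0 * t + i)  # strictly monotone in t -> rho 1
        names.append(f"CORE{i:02d}")
    for i in range(n_noise):
        rows.append(rng.normal(10, 3, size=n_cells) ** 2)
        names.append(f"NOISE{i:02d}")
    return ExpressionMatrix(np.abs(np.vstack(rows)), names,
                            [f"c{j}" for j in range(n_cells)], "log2tpm1")


class TestCoreSignature:
    def test_planted_followers_are_the_core(self):
        m = planted_core_matrix()
        res = core_signature(m, n=14)
        assert res.core == frozenset(f"CORE{i:02d}" for i in range(11))

    def test_targets_never_in_core(self, core42):
        assert not ({"POU4F2", "ISL1", "SNCG", "RBPMS"} & set(core42.core))

    def test_core_subset_of_every_top_list(self, core42):
        for sym, lst in core42.lists.items():
            assert core42.core <= set(lst.genes[:core42.n])

    def test_core_shrinks_as_targets_are_added(self, log_tpm42):
        sizes = [len(core_signature(log_tpm42, targets=t, n=200).core)
                 for t in (("BRN3B", "SNCG"),
                           ("BRN3B", "SNCG", "ISL1"),
                           ("BRN3B", "SNCG", "ISL1", "RBPMS"))]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_mutually_exclusive_targets_give_empty_core(self):
        rng = np.random.default_rng(5)
        n = 60
        groups = np.repeat([0, 1, 2, 3], n // 4)
        rows, names = [], []
        for g, sym in enumerate(("POU4F2", "ISL1", "SNCG", "RBPMS")):
            rows.append(np.where(groups == g, 50.0, 0.0)
                        + rng.normal(0, 0.5, n) ** 2)
            names.append(sym)
        for i in range(40):
            rows.append(rng.normal(5, 2, n) ** 2)
            names.append(f"N{i:02d}")
        m = ExpressionMatrix(np.vstack(rows), names,
                             [f"c{j}" for j in range(n)], "log2tpm1")
        res = core_signature(m, n=10)
        assert len(res.core) <= 1

    def test_unresolved_target_is_config_error(self, random_matrix):
        with pytest.raises(ConfigError, match="BRN3B"):
            core_signature(random_matrix(n_genes=10, n_cells=8, seed=0), n=3)


class TestRecoveryOnMosaic:
    def test_core_recovers_planted_pan_module(self, mosaic42, core42):
        _, truth = mosaic42
        rec = marker_recovery(core42.core, truth.pan_truth)
        assert rec.precision >= 0.95
        assert rec.recall >= 0.95

    def test_ds_candidates_recover_planted_ds_module(self, mosaic42, ds42):
        _, truth = mosaic42
        rec = marker_recovery(ds42.core, truth.ds_truth)
        assert rec.recall >= 0.95

    def test_candidate_set_bounded_by_list_length(self, log_tpm42):
        res = subtype_candidates(log_tpm42, n=50)
        assert len(res.core) <= 50


class TestMarkerRecovery:
    def test_exact_match(self):
        rec = marker_recovery({"a", "b"}, {"a", "b"})
        assert (rec.precision, rec.recall) == (1.0, 1.0)

    def test_counting(self):
        truth = {f"t{i}" for i in range(10)}
        result = set(list(truth)[:8]) | {f"x{i}" for i in range(12)}
        rec = marker_recovery(result, truth)
        assert rec.precision == pytest.approx(0.4)
        assert rec.recall == pytest.approx(0.8)

    def test_disjoint(self):
        rec = marker_recovery({"a"}, {"b"})
        assert (rec.precision, rec.recall) == (0.0, 0.0)

    def test_empty_result_has_undefined_precision(self):
        rec = marker_recovery(set(), {"a"})
        assert rec.precision is None and rec.recall == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(UsageError):
            marker_recovery({"a"}, set())


class TestSpecificityContrast:
    def test_identical_panel_gene_fails_verdict(self):
        rng = np.random.default_rng(2)
        t = rng.normal(10, 3, 30) ** 2
        rows = [t, 2 * t + 1] + [rng.normal(5, 2, 30) ** 2 for _ in range(20)]
        names = ["FSTL4", "TWIN"] + [f"N{i}" for i in range(20)]
        m = ExpressionMatrix(np.vstack(rows), names,
                             [f"c{j}" for j in range(30)], "log2tpm1")
        panel = MarkerPanel("twin", "negative_panel", ["TWIN"])
        rep = specificity_contrast(m, "FSTL4", [panel], n=10)
        # maximal up to the each-list-excludes-its-own-target convention
        assert rep.contrasts[0].overlap_counts["TWIN"] >= 9
        assert not rep.minimal_overlap

    def test_disjoint_planted_populations_pass(self, log_tpm42, panels):
        negatives = [panels[k] for k in ("progenitor", "rpe", "photoreceptor")]
        rep = specificity_contrast(log_tpm42, "FSTL4", negatives, n=200)
        assert rep.minimal_overlap
        for contrast in rep.contrasts:
            assert max(contrast.overlap_counts.values()) <= 0.05 * 200
            assert not contrast.unresolved

    def test_unresolvable_panel_is_config_error(self, random_matrix):
        m = random_matrix(n_genes=10, n_cells=8, seed=1)
        panel = MarkerPanel("ghost", "negative_panel", ["ABSENT1", "ABSENT2"])
        with pytest.raises(ConfigError, match="ghost"):
            specificity_contrast(m, "G0", [panel], n=3)


class TestValidateCandidate:
    def _toy(self):
        # candidate expressed in exactly the subtype-panel cells
        on = np.array([1.0] * 10 + [0.0] * 20)
        other = np.array([0.0] * 10 + [1.0] * 10 + [0.0] * 10)
        rng = np.random.default_rng(3)
        noise = rng.random(30)
        return ExpressionMatrix(
            np.vstack([on, on * (2 + noise), other, noise + 0.5]),
            ["CAND", "SUB", "OTHER", "HK"],
            [f"c{j}" for j in range(30)], "log2tpm1")

    def test_exact_coexpression_gives_unit_fractions(self):
        m = self._toy()
        res = validate_candidate(
            m, "CAND", MarkerPanel("sub", "subtype_panel", ["SUB"]),
            [MarkerPanel("neg", "negative_panel", ["OTHER"])])
        assert res.subtype_fractions["SUB"] == 1.0
        assert res.other_fractions["neg"]["OTHER"] == 0.0
        assert res.passed

    def test_planted_dcx_like_gene_passes(self, log_tpm42, panels):
        others = [panels[k] for k in ("progenitor", "rpe", "photoreceptor")]
        res = validate_candidate(log_tpm42, "DCX", panels["on_ds"], others,
                                 detection_quantile=0.75)
        assert res.passed

    def test_ubiquitous_gene_fails(self, log_tpm42, panels):
        others = [panels[k] for k in ("progenitor", "rpe", "photoreceptor")]
        res = validate_candidate(log_tpm42, "BG0001", panels["on_ds"], others,
                                 detection_quantile=0.75)
        assert not res.passed

    def test_undetected_candidate_is_degenerate(self):
        m = ExpressionMatrix(np.array([[0.0, 0.0, 0.0], [1, 2, 3]]),
                             ["CAND", "SUB"], ["a", "b", "c"], "log2tpm1")
        with pytest.raises(DegenerateInputError):
            validate_candidate(m, "CAND",
                               MarkerPanel("s", "subtype_panel", ["SUB"]), [])
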