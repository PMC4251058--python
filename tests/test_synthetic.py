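"""Simulator ground truth, VCF round-trips, determinism, pipeline recovery."""

import json
import math

import numpy as np
import pytest

from clonaltrack.consensus import build_consensus
from clonaltrack.diversity import diversity_report
from clonaltrack.errors import ConfigurationError
from clonaltrack.pipeline import config_from_manifest, run_pipeline
from clonaltrack.quantify import apply_filters, quantify_variants
from clonaltrack.synthetic import (
    CallerSpec, ClonePlan, SimConfig, default_callers, default_clone_plans,
    emit_caller_vcfs, emit_cn_segments, simulate_clonal_structure,
    simulate_serial_study,
)
from clonaltrack.variant_io import read_caller_vcf, read_cn_segments


def zero_error_cfg(seed=0, **kw):
    return SimConfig(seed=seed, callers=default_callers(0.0, 0.0), **kw)


class TestClonalStructure:
    def test_expected_vaf_closed_form(self):
        assert ClonePlan("c", 1.0, 5, cn=2).expected_vaf == 0.5
        assert ClonePlan("c", 0.4, 5, cn=2).expected_vaf == 0.2
        assert ClonePlan("c", 0.6, 5, cn=3, multiplicity=2).expected_vaf == pytest.approx(0.4)

    def test_impossible_vaf_rejected(self):
        with pytest.raises(ConfigurationError, match="VAF"):
            simulate_clonal_structure(
                [ClonePlan("c", 1.0, 3, cn=1, multiplicity=2, fates=(True, True, True))],
                SimConfig(seed=0),
            )

    def test_deterministic_given_seed(self):
        plans = default_clone_plans()
        t1 = simulate_clonal_structure(plans, SimConfig(seed=5))
        t2 = simulate_clonal_structure(plans, SimConfig(seed=5))
        assert t1.variants.equals(t2.variants)
        assert t1.observations.equals(t2.observations)

    def test_fate_vector_length_checked(self):
        with pytest.raises(ConfigurationError, match="fate"):
            simulate_clonal_structure(
                [ClonePlan("c", 0.5, 3, fates=(True,))], SimConfig(seed=0, n_samples=3))

    def test_vaf_estimation_unbiased_at_binomial_scale(self):
        # across >=1000 variants at depth ~100, observed VAFs are unbiased and
        # their spread stays at the binomial sampling scale:
        # MAD ~= sqrt(2/pi) * sqrt(p(1-p)/n)
        p = 0.4
        plans = [ClonePlan("big", 2 * p, 1000, cn=2, fates=(True,))]
        cfg = SimConfig(seed=1, n_samples=1, chrom_lengths={"1": 10_000_000})
        truth = simulate_clonal_structure(plans, cfg)
        obs = truth.observations
        vafs = obs["trv"] / (obs["trv"] + obs["trr"])
        assert abs(float(vafs.mean()) - p) < 0.005
        theoretical_mad = np.sqrt(2 / np.pi) * np.sqrt(p * (1 - p) / cfg.mean_depth)
        assert float(np.mean(np.abs(vafs - p))) < 1.25 * theoretical_mad


class TestEmission:
    def test_zero_error_callers_agree_exactly(self, tmp_path):
        cfg = zero_error_cfg(seed=2)
        truth = simulate_clonal_structure(default_clone_plans(), cfg)
        paths = emit_caller_vcfs(truth, cfg, tmp_path, sample_index=0)
        key_sets = []
        for caller, spec in zip(paths, cfg.callers):
            recs = read_caller_vcf(paths[caller], spec.dialect, caller_id=caller)
            key_sets.append({r.key for r in recs})
        assert key_sets[0] == key_sets[1] == key_sets[2]
        assert len(key_sets[0]) == len(truth.expected_keys(0))

    def test_round_trip_reproduces_planted_counts(self, tmp_path):
        cfg = zero_error_cfg(seed=3)
        truth = simulate_clonal_structure(default_clone_plans(), cfg)
        paths = emit_caller_vcfs(truth, cfg, tmp_path, sample_index=1)
        obs = truth.observations
        obs_s = obs[obs["sample_index"] == 1].merge(truth.variants, on="variant_id")
        planted = {row["key"]: (row["trv"], row["trr"]) for _, row in obs_s.iterrows()}
        for spec in cfg.callers:
            recs = read_caller_vcf(paths[spec.caller_id], spec.dialect)
            got = {f"{r.key.chrom}:{r.key.pos}:{r.key.ref}>{r.key.alt}": (r.trv, r.trr)
                   for r in recs}
            assert got == planted

    def test_full_dropout_leaves_header_only(self, tmp_path):
        cfg = SimConfig(seed=4, callers=(CallerSpec("gone", "allele_depths", fn_rate=1.0),))
        truth = simulate_clonal_structure(default_clone_plans(), cfg)
        paths = emit_caller_vcfs(truth, cfg, tmp_path, sample_index=0)
        assert read_caller_vcf(paths["gone"], "allele_depths") == []

    def test_segments_cover_every_planted_variant(self, tmp_path):
        plans = [
            ClonePlan("a", 1.0, 20, cn=2, fates=(True,)),
            ClonePlan("b", 0.5, 20, cn=3, fates=(True,)),
        ]
        cfg = SimConfig(seed=5, n_samples=1)
        truth = simulate_clonal_structure(plans, cfg)
        segs = read_cn_segments(emit_cn_segments(truth, tmp_path / "cn.tsv"))
        cn_by_clone = {"a": 2, "b": 3}
        for _, v in truth.variants.iterrows():
            containing = [s for s in segs if s.chrom == v["chrom"] and s.contains(v["pos"])]
            assert len(containing) == 1
            assert containing[0].cn == cn_by_clone[v["clone"]]


class TestSerialStudy:
    def test_bundle_layout_and_manifest(self, tmp_path):
        manifest = simulate_serial_study(cfg=SimConfig(seed=6), out_dir=tmp_path / "b")
        assert len(manifest["samples"]) == 3
        base = tmp_path / "b"
        for s in manifest["samples"]:
            assert len(s["vcfs"]) == 3
            for p in s["vcfs"].values():  # manifest paths are bundle-relative
                assert (base / p).exists()
            assert (base / s["segments"]).exists()
        truth = json.loads((tmp_path / "b" / "truth.json").read_text())
        assert {t["from"] for t in truth["evolution"]["transitions"]} == {"S1", "S2"}

    def test_byte_identical_given_seed(self, tmp_path):
        simulate_serial_study(cfg=SimConfig(seed=7), out_dir=tmp_path / "x")
        simulate_serial_study(cfg=SimConfig(seed=7), out_dir=tmp_path / "y")
        for px in sorted((tmp_path / "x").rglob("*")):
            if px.is_file():
                py = tmp_path / "y" / px.relative_to(tmp_path / "x")
                assert px.read_bytes() == py.read_bytes(), px.name

    def test_different_seeds_differ(self, tmp_path):
        m1 = simulate_serial_study(cfg=SimConfig(seed=1), out_dir=tmp_path / "a")
        m2 = simulate_serial_study(cfg=SimConfig(seed=2), out_dir=tmp_path / "b")
        t1 = (tmp_path / "a" / "truth.json").read_text()
        t2 = (tmp_path / "b" / "truth.json").read_text()
        assert t1 != t2

    def test_identical_samples_have_empty_gain_and_dead_sets(self, tmp_path):
        plans = [ClonePlan("stable", 1.0, 10, fates=(True, True))]
        manifest = simulate_serial_study(plans, SimConfig(seed=8, n_samples=2),
                                         tmp_path / "b")
        truth = json.loads((tmp_path / "b" / "truth.json").read_text())
        (t,) = truth["evolution"]["transitions"]
        assert t["gained"] == [] and t["dead_pool"] == []
        assert len(t["survived"]) == 10


class TestPipelineRecovery:
    def test_zero_error_bundle_recovers_planted_fates_exactly(self, tmp_path):
        cfg = zero_error_cfg(seed=9)
        manifest = simulate_serial_study(default_clone_plans(), cfg, tmp_path / "b")
        summary = run_pipeline(
            config_from_manifest(manifest, base_dir=tmp_path / "b", make_plots=False),
            tmp_path / "out")
        truth = json.loads((tmp_path / "b" / "truth.json").read_text())
        evo_path = tmp_path / "out" / "evolution.json"
        observed = json.loads(evo_path.read_text())
        for t_obs, t_true in zip(observed["transitions"], truth["evolution"]["transitions"]):
            assert t_obs["survived"] == t_true["survived"]
            assert t_obs["gained"] == t_true["gained"]
            assert t_obs["dead_pool"] == t_true["dead_pool"]

    def test_equal_abundance_species_recover_log_k_diversity(self, tmp_path):
        k = 60
        plans = [ClonePlan("founder", 1.0, k, cn=2, fates=(True,))]
        cfg = zero_error_cfg(seed=10, n_samples=1)
        truth = simulate_clonal_structure(plans, cfg)
        paths = emit_caller_vcfs(truth, cfg, tmp_path, sample_index=0)
        caller_sets = {c.caller_id: read_caller_vcf(paths[c.caller_id], c.dialect,
                                                    caller_id=c.caller_id)
                       for c in cfg.callers}
        consensus = build_consensus(caller_sets, rule="majority")
        segs = read_cn_segments(emit_cn_segments(truth, tmp_path / "cn.tsv"))
        filtered = apply_filters(quantify_variants(consensus, segs))
        rep = diversity_report(filtered)
        assert rep.n_variants == k
        assert abs(rep.shannon - math.log(k)) < 0.05
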