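import hashlib
from pathlib import Path

import numpy as np
import pytest

from psimeth.io_formats import read_allc, read_de_table, read_features, read_sample_sheet
from psimeth.methylation_core import estimate_nonconversion
from psimeth.synthetic_data import (
    Implant,
    SimConfig,
    default_root_design,
    persistence_design,
    simulate_annotation,
    simulate_de_table,
    simulate_methylomes,
    simulate_site_mixture,
    write_dataset,
)


def small_cfg(**kw):
    defaults = dict(
        genome={"chr1": 80_000, "chr2": 40_000},
        n_genes=8, n_tes=12, n_background_sites=200, sites_per_te=8,
        n_spike_sites=150, seed=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestAnnotation:
    def test_genes_disjoint_and_within_genome(self):
        cfg = small_cfg()
        genes, tes = simulate_annotation(cfg)
        for c in cfg.genome:
            spans = sorted((g.start, g.end) for g in genes if g.chrom == c)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2
            for s, e in spans:
                assert 1 <= s <= e <= cfg.genome[c]

    def test_te_class_mix_degenerate(self):
        cfg = small_cfg(te_class_mix={"MITE": 1.0})
        _, tes = simulate_annotation(cfg)
        assert tes and all(t.te_class == "MITE" for t in tes)

    def test_seeded_determinism(self):
        a = simulate_annotation(small_cfg())
        b = simulate_annotation(small_cfg())
        assert a == b


class TestMethylomes:
    def test_design_sizes(self):
        assert len(default_root_design()) == 18
        assert len({s.sample_id for s in default_root_design()}) == 18
        assert len(persistence_design()) == 9

    def test_spike_in_matches_nc_rate(self):
        """Observed spike-in level within 3 SE of the configured 0.5%."""
        cfg = small_cfg(n_spike_sites=400)
        genes, tes = simulate_annotation(cfg)
        ms, _ = simulate_methylomes(cfg, genes, tes)
        _, spike = ms.split_spike_in()
        nc = estimate_nonconversion(spike)
        se = np.sqrt(cfg.nc_rate * (1 - cfg.nc_rate) / nc.n_basecalls)
        assert abs(nc.rate - cfg.nc_rate) < 3 * se
        assert nc.n_basecalls > 100_000

    def test_implant_group_difference(self):
        """Group-mean observed difference ~= delta * (1 - nc) at the implant."""
        cfg = small_cfg(implants=[Implant(delta=0.5, n_sites=12)], coverage_mean=40)
        genes, tes = simulate_annotation(cfg)
        ms, truth = simulate_methylomes(cfg, genes, tes)
        tr = truth[0]
        region = ms.subset_region(tr.chrom, tr.start, tr.end)
        labels = np.array([s.condition for s in ms.samples])
        lv = {}
        for g in ("plus_pi", "minus_pi"):
            cols = labels == g
            lv[g] = region.mc[:, cols].sum() / region.total[:, cols].sum()
        diff = lv["minus_pi"] - lv["plus_pi"]
        assert diff == pytest.approx(0.5 * (1 - cfg.nc_rate), abs=0.05)

    def test_implants_live_in_tes_near_genes(self):
        cfg = small_cfg(implants=[Implant() for _ in range(3)])
        genes, tes = simulate_annotation(cfg)
        _, truth = simulate_methylomes(cfg, genes, tes)
        te_by_id = {t.id: t for t in tes}
        for tr in truth:
            assert tr.te_overlap and tr.context == "CHH"
            te = te_by_id[tr.te_id]
            assert te.start <= tr.start and tr.end <= te.end + 200
            assert tr.nearest_gene

    def test_zero_dispersion_is_binomial(self):
        """With dispersion 0 the across-sample variance of null-site counts
        collapses to the binomial level."""
        cfg_d = small_cfg(dispersion=0.15, implants=[], n_background_sites=600)
        cfg_0 = small_cfg(dispersion=0.0, implants=[], n_background_sites=600)
        var = {}
        for name, cfg in (("d", cfg_d), ("0", cfg_0)):
            genes, tes = simulate_annotation(cfg)
            ms, _ = simulate_methylomes(cfg, genes, tes)
            genome, _ = ms.split_spike_in()
            chh = genome.subset_context("CHH")
            frac = np.divide(chh.mc, chh.total, out=np.full(chh.mc.shape, np.nan),
                             where=chh.total > 0)
            var[name] = np.nanvar(frac, axis=1).mean()
        assert var["d"] > 2 * var["0"]

    def test_beta_binomial_moments(self):
        """Mean within 3 SE and variance inflated by ~1 + (n-1)*rho."""
        rho, p, cov = 0.05, 0.3, 30
        cfg = small_cfg(
            dispersion=rho, coverage_mean=cov, implants=[], n_background_sites=2000,
            n_tes=0, n_genes=2, sites_per_te=0, nc_rate=0.0,
            baseline_levels={(c, f): p for c in ("CG", "CHG", "CHH") for f in (True, False)},
        )
        genes, tes = simulate_annotation(cfg)
        ms, _ = simulate_methylomes(cfg, genes, tes)
        genome, _ = ms.split_spike_in()
        mc, tot = genome.mc.ravel(), genome.total.ravel()
        keep = tot > 0
        mc, tot = mc[keep], tot[keep]
        mean = mc.sum() / tot.sum()
        assert mean == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / tot.sum()) + 0.003)
        # dispersion check on fixed-coverage subset
        fixed = tot == cov
        inflation = np.var(mc[fixed] / cov) / (p * (1 - p) / cov)
        expected = 1 + (cov - 1) * rho
        assert inflation == pytest.approx(expected, rel=0.15)


class TestSiteMixture:
    def test_shapes_and_truth_mask(self):
        sites, mc, total, truth, labels = simulate_site_mixture(
            n_sites=300, n_per_group=3, seed=1
        )
        assert mc.shape == total.shape == (300, 6)
        assert truth.sum() == 30
        assert labels == ["control"] * 3 + ["stress"] * 3

    def test_null_sites_share_common_proportion(self):
        """Group means at null sites coincide up to binomial noise; truly
        differential sites separate by ~0.5."""
        sites, mc, total, truth, labels = simulate_site_mixture(
            n_sites=2000, n_per_group=9, coverage_mean=50, seed=2
        )
        lab = np.array(labels)
        lv = {}
        for g in ("control", "stress"):
            cols = lab == g
            lv[g] = mc[:, cols].sum(axis=1) / np.maximum(total[:, cols].sum(axis=1), 1)
        diff = lv["stress"] - lv["control"]
        assert abs(diff[~truth].mean()) < 0.005
        assert diff[truth].mean() == pytest.approx(0.5, abs=0.03)

    def test_determinism(self):
        a = simulate_site_mixture(n_sites=50, seed=9)
        b = simulate_site_mixture(n_sites=50, seed=9)
        assert (a[1] == b[1]).all() and (a[2] == b[2]).all()


class TestWriteDataset:
    def _digest(self, root: Path) -> str:
        h = hashlib.sha256()
        for p in sorted(root.rglob("*")):
            if p.is_file():
                h.update(p.relative_to(root).as_posix().encode())
                h.update(p.read_bytes())
        return h.hexdigest()

    def test_byte_identical_reruns_and_readable(self, tmp_path):
        cfg = small_cfg(implants=[Implant(delta=0.5)])
        p1 = write_dataset(cfg, tmp_path / "a")
        write_dataset(cfg, tmp_path / "b")
        assert self._digest(tmp_path / "a") == self._digest(tmp_path / "b")

        metas, allc_paths = read_sample_sheet(p1["sample_sheet"])
        assert len(metas) == 18
        sheet_dir = Path(p1["sample_sheet"]).parent
        df = read_allc(sheet_dir / allc_paths[metas[0].sample_id])
        assert (df["total_reads"] > 0).all()
        genes = read_features(p1["genes"], "gene")
        tes = read_features(p1["tes"], "te")
        assert genes and tes
        de = read_de_table(p1["de"])
        assert len(de) == len(genes)

    def test_de_correlation_switch(self, tmp_path):
        cfg = small_cfg(implants=[Implant() for _ in range(4)], de_prob=1.0)
        genes, tes = simulate_annotation(cfg)
        _, truth = simulate_methylomes(cfg, genes, tes)
        de = {r.gene_id: r for r in simulate_de_table(cfg, genes, truth)}
        for tr in truth:
            rec = de[tr.nearest_gene]
            assert rec.qvalue < 0.05 and 2 ** rec.log2fc > 2

        cfg0 = small_cfg(implants=[Implant() for _ in range(4)], de_prob=0.0)
        de0 = simulate_de_table(cfg0, genes, truth)
        assert all(r.qvalue >= 0.05 for r in de0)
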