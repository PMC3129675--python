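"""Window scanning against a brute-force oracle, locus merging and
classification rules."""

import numpy as np
import pytest

from imprintscan.config import RunConfig
from imprintscan.io import GeneModel, SnpDef
from imprintscan.normalization import AEPoint
from imprintscan.phasing import TransmissionObservation
from imprintscan.scan import (
    Locus,
    SiteTransmission,
    Window,
    annotate_extension,
    classify_locus,
    classify_transmission,
    detect_partial_imprinting,
    merge_windows_to_loci,
    scan_windows,
)


def _panel(mags_by_child, positions=None, chrom="chr1"):
    """Build (ae_by_child, snps) from per-child magnitude lists (None = not
    informative)."""
    n = len(next(iter(mags_by_child.values())))
    positions = positions or [1000 + 2000 * i for i in range(n)]
    snps = [SnpDef(chrom, pos, f"s{i}") for i, pos in enumerate(positions)]
    ae = {}
    for child, mags in mags_by_child.items():
        pts = {}
        for i, m in enumerate(mags):
            if m is None:
                continue
            ratio = float(m)
            pts[f"s{i}"] = AEPoint(child, f"s{i}", 0.5, ratio, float(m),
                                   "A" if m > 1 else None, True)
        ae[child] = pts
    return ae, snps


from oracles import brute_force_windows


def test_three_snp_window_above_threshold(config):
    ae, snps = _panel({
        "c1": [3.0, 3.1, 2.8],
        "c2": [3.2, 3.0, 2.95],
    })
    ws = scan_windows(ae, snps, config)
    assert len(ws) == 1
    assert ws[0].snp_ids == ("s0", "s1", "s2")
    assert ws[0].per_child_magnitude["c1"] == pytest.approx(2.9666, abs=1e-3)
    assert set(ws[0].qualifying_children) == {"c1", "c2"}


def test_two_snps_or_one_child_do_not_qualify(config):
    ae, snps = _panel({"c1": [5.0, 5.0], "c2": [5.0, 5.0]})
    assert scan_windows(ae, snps, config) == []
    ae, snps = _panel({"c1": [5.0, 5.0, 5.0], "c2": [1.0, 1.0, 1.0]})
    assert scan_windows(ae, snps, config) == []


def test_exact_threshold_is_excluded(config):
    # "in excess of" the threshold: strictly greater
    ae, snps = _panel({"c1": [2.9, 2.9, 2.9], "c2": [2.9, 2.9, 2.9]})
    assert scan_windows(ae, snps, config) == []


def test_partial_band_excludes_extreme_means(config):
    ae, snps = _panel({"c1": [3.5, 3.5, 3.5], "c2": [3.5, 3.5, 3.5]})
    band = (config.partial_fold_low, config.partial_fold_high)
    assert scan_windows(ae, snps, config, fold_range=band) == []
    ae, snps = _panel({"c1": [2.4, 2.4, 2.4], "c2": [2.0, 2.5, 2.4]})
    ws = scan_windows(ae, snps, config, fold_range=band)
    assert len(ws) == 1  # inclusive at 2.0, exclusive at 2.9


def test_windows_break_at_large_gaps(config):
    positions = [1000, 3000, 5000, 200_000, 202_000, 204_000]
    ae, snps = _panel(
        {"c1": [8.0] * 6, "c2": [8.0] * 6}, positions=positions
    )
    ws = scan_windows(ae, snps, config)
    assert sorted(w.snp_ids for w in ws) == [
        ("s0", "s1", "s2"), ("s3", "s4", "s5")
    ]


def test_scan_equals_brute_force_oracle_on_random_instances(config):
    rng = np.random.default_rng(7)
    for case in range(60):
        n_snps = int(rng.integers(3, 25))
        n_children = int(rng.integers(2, 7))
        mags = {}
        for c in range(n_children):
            row = []
            for _ in range(n_snps):
                if rng.random() < 0.25:
                    row.append(None)
                else:
                    row.append(float(rng.choice([1.0, 1.5, 2.5, 3.5, 8.0])))
            mags[f"c{c}"] = row
        positions = sorted(rng.choice(np.arange(1, 300) * 1500, n_snps, replace=False))
        ae, snps = _panel(mags, positions=[int(p) for p in positions])
        for fold_range in ((config.extreme_fold, float("inf")),
                           (config.partial_fold_low, config.partial_fold_high)):
            got = sorted(w.snp_ids for w in scan_windows(ae, snps, config, fold_range))
            assert got == brute_force_windows(ae, snps, config, fold_range), f"case {case}"


def test_window_maximality(config):
    ae, snps = _panel({
        "c1": [8.0, 8.0, 8.0, 8.0, 1.0],
        "c2": [8.0, 8.0, 8.0, 8.0, 1.0],
    })
    ws = scan_windows(ae, snps, config)
    for w in ws:
        assert len(w.snp_ids) >= 4  # the 4-SNP high run must not be truncated


def _mk_window(chrom, start, end, mag=5.0):
    return Window(chrom, ("x",), start, end, {}, ("c1", "c2"), mag)


def test_merge_windows_gap_rule(config):
    near = [_mk_window("chr1", 1000, 2000), _mk_window("chr1", 12_000, 13_000)]
    assert len(merge_windows_to_loci(near, config)) == 1
    far = [_mk_window("chr1", 1000, 2000), _mk_window("chr1", 102_000, 103_000)]
    assert len(merge_windows_to_loci(far, config)) == 2
    other_chrom = [_mk_window("chr1", 1000, 2000), _mk_window("chr2", 3000, 4000)]
    assert len(merge_windows_to_loci(other_chrom, config)) == 2


def test_merge_equals_transitive_closure_oracle(config):
    rng = np.random.default_rng(13)
    for _ in range(50):
        wins = [
            _mk_window("chr1", int(s), int(s + rng.integers(500, 30_000)))
            for s in rng.integers(0, 500_000, rng.integers(2, 15))
        ]
        loci = merge_windows_to_loci(wins, config)
        # oracle: grow clusters to a fixed point
        clusters = [[w] for w in wins]
        changed = True
        while changed:
            changed = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any(
                        a.start <= b.end + config.merge_gap_bp
                        and b.start <= a.end + config.merge_gap_bp
                        for a in clusters[i] for b in clusters[j]
                    ):
                        clusters[i] += clusters.pop(j)
                        changed = True
                        break
                if changed:
                    break
        expected = sorted(
            (min(w.start for w in cl), max(w.end for w in cl)) for cl in clusters
        )
        assert sorted((l.start, l.end) for l in loci) == expected


def _trans(child, origin, mag=5.0):
    return TransmissionObservation(child, "L", origin, mag)


def test_classify_transmission_rules(config):
    all_pat = [_trans(f"c{i}", "paternal") for i in range(4)]
    assert classify_transmission(all_pat, config) == "imprinted_paternal_expressed"
    all_mat = [_trans(f"c{i}", "maternal") for i in range(3)]
    assert classify_transmission(all_mat, config) == "imprinted_maternal_expressed"
    mixed = all_pat[:3] + [_trans("c9", "maternal")]
    assert classify_transmission(mixed, config) == "inconsistent"
    single = [_trans("c0", "paternal"), _trans("c1", "unknown")]
    assert classify_transmission(single, config) == "non_transmitted"


def test_classify_transmission_invariant_to_child_order(config):
    obs = [_trans("a", "paternal"), _trans("b", "paternal"), _trans("c", "maternal")]
    for perm in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
        assert classify_transmission([obs[i] for i in perm], config) == "inconsistent"


def test_positive_mapping_overrides_imprinted_call():
    locus = Locus("L", "chr1", 100, 200, ("s0",))
    assert classify_locus(locus, "imprinted_paternal_expressed", True).classification == "heritable"
    assert (
        classify_locus(locus, "imprinted_maternal_expressed", False).classification
        == "imprinted_maternal_expressed"
    )
    assert classify_locus(locus, "inconsistent", False).classification == "inconsistent"


def _moderate_locus(locus_id="M", chrom="chr1", start=500_000, end=520_000):
    return Locus(locus_id, chrom, start, end, ("s0", "s1", "s2"), mean_magnitude=2.4)


def _partial_inputs(origin="paternal", alleles=("A", "B")):
    trans = [TransmissionObservation(f"c{i}", "M", origin, 2.4) for i in range(3)]
    sites = [
        SiteTransmission(f"c{i}", f"s{i % 3}", origin, alleles[i % len(alleles)], 2.4)
        for i in range(3)
    ]
    return {"M": trans}, {"M": sites}


def test_partial_imprinting_detection(config):
    locus = _moderate_locus()
    trans, sites = _partial_inputs()
    got = detect_partial_imprinting([locus], [], {"M": False}, trans, sites, config)
    assert [l.classification for l in got] == ["partial_imprinting"]


def test_partial_excluded_inside_classic_locus(config):
    locus = _moderate_locus()
    classic = Locus("C", "chr1", 498_000, 530_000, (), classification="imprinted_paternal_expressed")
    trans, sites = _partial_inputs()
    assert detect_partial_imprinting([locus], [classic], {"M": False}, trans, sites, config) == []


def test_partial_excluded_when_mapped_or_allele_fixed(config):
    locus = _moderate_locus()
    trans, sites = _partial_inputs()
    assert detect_partial_imprinting([locus], [], {"M": True}, trans, sites, config) == []
    trans, sites = _partial_inputs(alleles=("A",))  # one fixed allele label
    assert detect_partial_imprinting([locus], [], {"M": False}, trans, sites, config) == []


def test_annotate_extension(config):
    genes = [GeneModel("g", "chr1", 10_000, 20_000)]
    inside = Locus("a", "chr1", 15_000, 16_000, ())
    near = Locus("b", "chr1", 22_000, 23_000, ())  # 2 kb downstream
    far = Locus("c", "chr1", 28_500, 29_000, ())  # 8.5 kb away
    assert annotate_extension(inside, genes, config) == "within_gene"
    assert annotate_extension(near, genes, config) == "within_extension"
    assert annotate_extension(far, genes, config) == "beyond_extension"
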