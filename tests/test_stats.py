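"""Group statistics, histograms, outlier flags and report export."""

import numpy as np
import pandas as pd
import pytest

from burgidunitz.geometry import AttackGeometry
from burgidunitz.pipeline import (
    CaseResult,
    FilterStatus,
    ManifestEntry,
    parse_atom_address,
    parse_residue_address,
)
from burgidunitz.stats import (
    class_table,
    export_report,
    flag_outliers,
    histogram,
    results_to_frame,
    summarize,
)


def _case(phi=90.0, alpha_bd=90.0, alpha_fl=10.0, d=2.9, clazz=1, subtype="II",
          role="primary", kind="L-ASN", included=True, structure_id="x",
          swap=False):
    entry = ManifestEntry(
        structure_id=structure_id, path=f"{structure_id}.pdb",
        asparaginase_class=clazz, subtype=subtype, chain_id="A",
        primary_nucleophile=parse_atom_address("A/THR/12/OG1"),
        ligand=parse_residue_address("A/ASN/900"), ligand_kind=kind,
        oxyanion_donors=(parse_atom_address("A/THR/12/N"),),
        resolution=1.8,
    )
    geometry = AttackGeometry(
        d=d, dp=0.3, alpha_bd=alpha_bd, alpha_fl=alpha_fl, alpha_lw=1.0,
        phi_attack=phi, tau=80.0, delta=0.0,
        chirality="S" if phi > 0 else "R", chiral_volume=np.sign(phi) * 8.0,
    )
    status = FilterStatus(included, () if included else ("reason",))
    return CaseResult(entry, role, geometry, swap, status)


class TestSummarize:
    def test_single_case_has_blank_sigma(self):
        (gs,) = summarize([_case()], by=("class",))
        assert gs.n == 1
        assert gs.stds["phi_attack"] is None
        assert gs.formatted("phi_attack") == "90.0"

    def test_hand_computed_mean_and_sample_sigma(self):
        cases = [_case(phi=p, structure_id=f"x{p}") for p in (80.0, 90.0, 100.0)]
        (gs,) = summarize(cases, by=("class",))
        assert gs.means["phi_attack"] == pytest.approx(90.0)
        assert gs.stds["phi_attack"] == pytest.approx(10.0)  # ddof=1
        assert gs.formatted("phi_attack") == "90.0 (10.0)"

    def test_indeterminate_fl_excluded_and_counted(self):
        cases = [
            _case(alpha_fl=20.0, structure_id="a"),
            _case(alpha_fl=None, structure_id="b"),
            _case(alpha_fl=40.0, structure_id="c"),
        ]
        (gs,) = summarize(cases, by=("class",))
        assert gs.means["alpha_fl"] == pytest.approx(30.0)
        assert gs.fl_indeterminate == 1
        assert gs.n == 3

    def test_excluded_cases_do_not_contribute(self):
        cases = [_case(structure_id="a"), _case(included=False, structure_id="b")]
        (gs,) = summarize(cases, by=("class",))
        assert gs.n == 1

    def test_permutation_invariance(self):
        cases = [_case(phi=p, structure_id=f"x{i}")
                 for i, p in enumerate((70.0, 85.0, 95.0, 110.0))]
        a = summarize(cases, by=("class",))
        b = summarize(list(reversed(cases)), by=("class",))
        assert a[0].means == b[0].means and a[0].stds == b[0].stds


class TestClassTable:
    def test_group_sizes_are_additive(self):
        cases = (
            [_case(subtype="I", structure_id=f"i{k}") for k in range(3)]
            + [_case(subtype="II", structure_id=f"ii{k}") for k in range(5)]
            + [_case(subtype="s", structure_id=f"s{k}") for k in range(2)]
            + [_case(clazz=2, subtype="none", phi=-83.0, structure_id=f"c2{k}")
               for k in range(2)]
        )
        table = {gs.label: gs for gs in class_table(cases)}
        assert table["class 1 type I"].n == 3
        assert table["class 1 type II"].n == 5
        assert table["class 1 type I + II"].n == 8
        assert table["class 1"].n == 10
        assert table["All"].n == 12

    def test_pooled_row_uses_absolute_phi(self):
        cases = [_case(phi=90.0, structure_id="a"),
                 _case(phi=-90.0, clazz=2, subtype="none", structure_id="b")]
        table = {gs.label: gs for gs in class_table(cases)}
        assert table["All"].means["phi_attack"] == pytest.approx(90.0)
        assert table["All"].abs_mean_phi

    def test_d_ligands_and_secondary_roles_are_not_pooled(self):
        cases = [
            _case(structure_id="a"),
            _case(kind="D-ASN", phi=-89.0, structure_id="b"),
            _case(role="secondary", structure_id="c"),
        ]
        table = {gs.label: gs for gs in class_table(cases)}
        assert table["All"].n == 1


class TestHistogram:
    def test_single_case_one_nonzero_bin(self):
        h = histogram([_case(phi=87.0)], "phi_attack", bin_width=5.0)
        total = sum(int(c.sum()) for c in h.counts.values())
        assert total == 1
        assert (h.bin_edges % 5.0 == 0).all()  # zero-aligned bins

    def test_counts_sum_to_group_sizes(self):
        cases = [_case(phi=70.0 + 7 * k, structure_id=f"x{k}") for k in range(6)]
        cases += [_case(role="secondary", phi=-120.0 + 11 * k, structure_id=f"y{k}")
                  for k in range(4)]
        h = histogram(cases, "phi_attack", bin_width=5.0)
        assert int(h.counts["primary"].sum()) == 6
        assert int(h.counts["secondary"].sum()) == 4

    def test_uniform_grid_gives_flat_counts(self):
        cases = [_case(phi=p, structure_id=f"u{i}")
                 for i, p in enumerate(np.arange(62.5, 122.5, 5.0))]
        h = histogram(cases, "phi_attack", bin_width=5.0)
        assert set(h.counts["primary"]) == {1}


class TestOutliers:
    def test_d_ligand_flagged_by_kind(self):
        cases = [_case(structure_id=f"x{k}") for k in range(5)]
        cases.append(_case(kind="D-ASN", phi=-89.0, structure_id="d1"))
        frame = flag_outliers(cases)
        flagged = frame[frame["outlier"]]
        assert list(flagged["structure_id"]) == ["d1"]
        assert list(flagged["outlier_rule"]) == ["d-ligand"]

    def test_large_deviation_flagged_by_sigma_rule(self):
        rng = np.random.default_rng(0)
        cases = [_case(phi=float(p), structure_id=f"x{i}")
                 for i, p in enumerate(rng.normal(90, 5, size=30))]
        cases.append(_case(phi=90.0 + 4 * 5.0 + 10, structure_id="far"))
        frame = flag_outliers(cases, k_sigma=3.0)
        far = frame[frame["structure_id"] == "far"].iloc[0]
        assert far["outlier"] and "sigma" in far["outlier_rule"]

    def test_separated_cluster_is_visible_in_histogram(self):
        # a wobbly sub-population near 110 deg separates from the 90-deg cluster
        cases = [_case(phi=float(p), structure_id=f"m{i}")
                 for i, p in enumerate((88, 89, 90, 91, 92, 90))]
        cases += [_case(phi=float(p), structure_id=f"w{i}")
                  for i, p in enumerate((109, 111))]
        h = histogram(cases, "phi_attack", bin_width=5.0)
        counts = h.counts["primary"]
        gap_bins = counts[(h.bin_edges[:-1] >= 95) & (h.bin_edges[:-1] < 105)]
        assert gap_bins.sum() == 0  # empty gap between the clusters
        assert counts[h.bin_edges[:-1] >= 105].sum() == 2


class TestExport:
    def test_empty_results_give_headers_only(self, tmp_path):
        paths = export_report([], [], [], tmp_path)
        cases = pd.read_csv(paths["cases"])
        assert len(cases) == 0
        assert "phi_attack" in cases.columns

    def test_csv_round_trip_to_three_decimals(self, tmp_path):
        cases = [_case(phi=87.123456, structure_id="p")]
        paths = export_report(summarize(cases, by=("class",)), [], cases, tmp_path)
        frame = pd.read_csv(paths["cases"])
        assert frame.loc[0, "phi_attack"] == pytest.approx(87.123, abs=5e-4)

    def test_table_shaped_group_csv(self, tmp_path, survey_results):
        table = class_table(survey_results)
        paths = export_report(table, [], survey_results, tmp_path)
        groups = pd.read_csv(paths["groups"])
        assert list(groups["group"])[:3] == [
            "class 1 type I", "class 1 type II", "class 1 type s",
        ]
        # mu (sigma) formatting
        assert "(" in groups.loc[0, "phi_attack"]
        report = paths["report"].read_text()
        assert "oxygen swaps   : 100" in report
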