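"""One test group per lint rule, plus engine behaviour."""

import pytest

from arklint.checks import (
    CHECKS,
    CheckConfig,
    check_characters,
    check_cohort_structure,
    check_depth,
    check_excluded_words,
    check_files_per_folder,
    check_formats,
    check_name_length,
    check_obscure_and_external,
    check_padding,
    check_path_length,
    check_path_repetition,
    check_periods,
    check_redundant_folders,
    check_root_hygiene,
    check_sibling_near_duplicates,
    run_checks,
)
from arklint.tree_model import read_manifest
from helpers import tree_of

CFG = CheckConfig()

LONG_TITLE = "A U Thör et al - A very long relevant title that has most of the keywords in your paper"


def by_path(findings, path):
    return [f for f in findings if path in f.paths]


class TestNameLength:
    def test_printed_long_folder_name_flagged(self):
        tree = tree_of(f"data/{LONG_TITLE}/x.tif")
        assert by_path(check_name_length(tree, CFG), f"data/{LONG_TITLE}")

    def test_boundary_inclusive(self):
        ok, bad = "n" * 50, "n" * 51
        tree = tree_of(f"data/{ok}", f"data/{bad}")
        findings = check_name_length(tree, CFG)
        assert not by_path(findings, f"data/{ok}")
        assert by_path(findings, f"data/{bad}")


class TestPathLength:
    def test_revised_path_not_flagged(self):
        tree = tree_of(
            "data/brief_description/treatment3_tissue/segmentation/organelle1_topology1.zip"
        )
        assert check_path_length(tree, CFG) == []

    def test_boundary_320(self):
        exact = "d/" + "x" * 318  # 320 characters in total
        over = "d/" + "x" * 319
        findings = check_path_length(tree_of(exact, over), CFG)
        assert {f.paths[0] for f in findings} == {over}

    def test_long_original_worked_path_flagged(self):
        # the original deposition path exceeds the legacy 320-char limit
        deep = "/".join(["data", LONG_TITLE, "A Folder with an overall description",
                         "0923480928 - Treatement Tr1-323 Tissue",
                         "0923480928 Treatement Tr1-323 Segmentation",
                         "0923480928 Treatement Tr1-323 Raw uncompressed TIFF slices",
                         "0923480928_Treatement_Tr1323_Organelle1-topology1.zip"])
        assert len(deep) > 320
        assert by_path(check_path_length(tree_of(deep), CFG), deep)


class TestDepth:
    def test_five_levels_flagged_four_clean(self):
        five = tree_of("a/b/c/d/e/x.tif")
        findings = check_depth(five, CFG)
        assert [f.paths[0] for f in findings] == ["a/b/c/d/e"]
        four = tree_of("a/b/c/d/x.tif")
        assert check_depth(four, CFG) == []

    def test_empty_tree_clean(self):
        assert check_depth(read_manifest([]), CFG) == []

    def test_root_exclusion_convention_configurable(self):
        cfg = CheckConfig(depth_counts_root=False)
        assert check_depth(tree_of("a/b/c/d/e/x.tif"), cfg) == []


class TestFilesPerFolder:
    def test_boundary_with_small_cap(self):
        cfg = CheckConfig(max_files_per_folder=5)
        ok = tree_of(*[f"d/sub/f{i}.tif" for i in range(5)])
        assert check_files_per_folder(ok, cfg) == []
        over = tree_of(*[f"d/sub/f{i}.tif" for i in range(6)])
        (finding,) = check_files_per_folder(over, cfg)
        assert finding.suggestion["split"]["n_subfolders"] == 2

    def test_million_file_message_names_hundred_children(self):
        cfg = CheckConfig(max_files_per_folder=10_000)
        tree = tree_of("d/sub/x.tif")
        folder = tree.find("d/sub")
        folder.children = [
            type(folder)(name=f"f{i}.tif", kind="file") for i in range(1_000_000)
        ]
        (finding,) = check_files_per_folder(tree, cfg)
        assert finding.suggestion["split"]["n_subfolders"] == 100
        assert "child00 to child99" in finding.message


class TestRedundantFolders:
    def test_single_child_chain_flagged_once(self):
        tree = tree_of(f"data/{LONG_TITLE}/A Folder with an overall description/x.tif")
        chains = [f for f in check_redundant_folders(tree, CFG) if "single folder" in f.message]
        assert len(chains) == 1
        assert chains[0].paths == ["data", f"data/{LONG_TITLE}"]

    def test_format_named_folder_flagged(self):
        tree = tree_of("d/condition/tiff/files1.tif", "d/condition/tiff/files2.tif")
        findings = check_redundant_folders(tree, CFG)
        assert any("restates the format" in f.message for f in findings)

    def test_two_format_folders_meaningful(self):
        tree = tree_of(
            "d/condition/tiff/a.tif",
            "d/condition/png/a.png",
        )
        findings = check_redundant_folders(tree, CFG)
        assert not any("restates the format" in f.message for f in findings)


class TestCharacters:
    def test_printed_name_space_nonascii_case(self):
        tree = tree_of(f"data/{LONG_TITLE}/x.tif")
        findings = by_path(check_characters(tree, CFG), f"data/{LONG_TITLE}")
        messages = " | ".join(f.message for f in findings)
        assert "spaces" in messages
        assert "'ö'" in messages and "U+00F6" in messages
        assert "uppercase" in messages

    def test_clean_revised_leaf(self):
        tree = tree_of("data/organelle1_topology1.zip")
        assert by_path(check_characters(tree, CFG), "data/organelle1_topology1.zip") == []

    def test_forbidden_characters_enumerated(self):
        tree = tree_of("d/what?now!")
        findings = by_path(check_characters(tree, CFG), "d/what?now!")
        assert sorted(f.suggestion["character"] for f in findings) == ["!", "?"]


class TestPeriods:
    @pytest.mark.parametrize("name", ["file.tar.gz", "file.ome.tiff", "file.ome.tf2",
                                      "file.ome.tf8", "file.ome.btf", "plain.zip", "noext"])
    def test_valid_extensions_clean(self, name):
        assert check_periods(tree_of(f"d/{name}"), CFG) == []

    def test_folder_with_periods_flagged(self):
        tree = tree_of("data/control.a.1.value/x.tif")
        (finding,) = check_periods(tree, CFG)
        assert finding.paths == ["data/control.a.1.value"]

    def test_stem_period_flagged(self):
        assert check_periods(tree_of("d/data.v1.zip"), CFG)


class TestExcludedWords:
    def test_token_match(self):
        (finding,) = check_excluded_words(tree_of("root/my_images/x.tif"), CFG)
        assert finding.paths == ["root/my_images"]

    def test_top_level_data_exempt(self):
        assert check_excluded_words(tree_of("data/x.tif"), CFG) == []

    def test_whole_token_only(self):
        assert check_excluded_words(tree_of("root/dataset_b/x.tif"), CFG) == []


class TestPathRepetition:
    def test_printed_worked_example_tokens(self):
        tree = tree_of(
            "data/0923480928 - Treatement Tr1-323 Tissue/0923480928_Treatement_Tr1323_x.zip"
        )
        findings = check_path_repetition(tree, CFG)
        tokens = sorted(f.suggestion["drop_token"] for f in findings)
        assert tokens == ["0923480928", "Treatement"]

    def test_nested_control_chain(self):
        tree = tree_of("data/control.a/control.a.1/control.a.1.value/")
        findings = check_path_repetition(tree, CFG)
        # 'control' repeats at two levels; 'a'/'1' are below the token length floor
        assert {f.suggestion["drop_token"] for f in findings} == {"control"}
        assert len(findings) == 2

    def test_revised_path_clean(self):
        tree = tree_of(
            "data/brief_description/treatment3_tissue/segmentation/organelle1_topology1.zip"
        )
        assert check_path_repetition(tree, CFG) == []


class TestSiblingNearDuplicates:
    def _variants(self, tree):
        return {
            (f.suggestion["a"], f.suggestion["b"], f.suggestion["variant"])
            for f in check_sibling_near_duplicates(tree, CFG)
        }

    def test_case_variant_tokens(self):
        tree = tree_of("d/t1/Topology/x.zip", "d/t2/topology/x.zip")
        assert ("Topology", "topology", "case") in self._variants(tree)

    def test_spelling_variant_tokens(self):
        tree = tree_of("d/Treatment one/x.zip", "d/Treatement two/x.zip")
        assert ("Treatement", "Treatment", "typo") in self._variants(tree)

    def test_separator_variant_tokens(self):
        tree = tree_of("d/Tr1-323 Tissue/Tr1323_x.zip")
        assert ("Tr1-323", "Tr1323", "separator") in self._variants(tree)

    def test_truncation_pair(self):
        tree = tree_of("d/tomo/a.mrc", "d/tomogram/b.mrc")
        assert ("tomo", "tomogram", "prefix") in self._variants(tree)

    def test_sequential_siblings_not_flagged(self):
        tree = tree_of(*[f"d/child{i:02d}/x.tif" for i in range(4)],
                       *[f"d/child00/s_{i:04d}.tif" for i in range(1, 5)])
        assert self._variants(tree) == set()

    def test_pair_reported_once(self):
        tree = tree_of("d/tomo/a.mrc", "d/tomogram/b.mrc")
        findings = check_sibling_near_duplicates(tree, CFG)
        pairs = [frozenset((f.suggestion["a"], f.suggestion["b"])) for f in findings]
        assert len(pairs) == len(set(pairs))


class TestCohortStructure:
    def _cohort_tree(self, extra_child: bool):
        lines = []
        for ident, spelling in [
            ("0923480928", "Treatement"),
            ("3738932082", "Treatment"),
            ("5647382910", "Treatment"),
            ("8812304956", "Treatment"),
        ]:
            base = f"d/{ident} - {spelling} Tissue"
            lines.append(f"{base}/Raw/slice-01.tif")
            lines.append(f"{base}/result.zip")
        if extra_child:
            lines.append("d/3738932082 - Treatment Tissue extra/x.tif")
            lines = [l for l in lines]
        return lines

    def test_pattern_breaker_flagged(self):
        lines = []
        for ident in ("0923480928", "3738932082", "5647382910", "8812304956"):
            base = f"d/{ident} - Treatment Tissue"
            lines.append(f"{base}/Raw/slice-01.tif")
            lines.append(f"{base}/result.zip")
        lines.append("d/3738932082 - Treatment Tissue/Old Analysis/notes.txt")
        findings = check_cohort_structure(read_manifest(lines), CFG)
        assert [f.paths[0] for f in findings] == ["d/3738932082 - Treatment Tissue"]

    def test_unanimous_cohort_clean(self):
        lines = []
        for ident in ("aaa", "bbb", "ccc"):
            lines.append(f"d/{ident} treatment/raw/x.tif")
        assert check_cohort_structure(read_manifest(lines), CFG) == []

    def test_cohort_of_two_never_flagged(self):
        lines = [
            "d/aaa treatment/raw/x.tif",
            "d/bbb treatment/raw/y.tif",
            "d/bbb treatment/extra/z.tif",
        ]
        assert check_cohort_structure(read_manifest(lines), CFG) == []


class TestObscureAndExternal:
    def test_obscure_identifier(self):
        tree = tree_of("d/0923480928 - Treatement Tr1-323 Tissue/x.tif")
        findings = check_obscure_and_external(tree, CFG)
        assert any(
            f.suggestion == {"pattern": "digit_run", "text": "0923480928"}
            for f in findings
        )

    def test_figure_reference(self):
        findings = check_obscure_and_external(tree_of("d/Figure 5/x.tif"), CFG)
        assert any(f.suggestion["pattern"] == "figure_ref" for f in findings)

    def test_et_al_personal_identifier(self):
        tree = tree_of(f"data/{LONG_TITLE}/x.tif")
        findings = check_obscure_and_external(tree, CFG)
        assert any(f.suggestion == {"pattern": "personal_id", "text": "et al"} for f in findings)

    def test_blocklist_match(self):
        cfg = CheckConfig(personal_id_blocklist={"asmith"})
        findings = check_obscure_and_external(tree_of("d/asmith_scans/x.tif"), cfg)
        assert any(f.suggestion["pattern"] == "personal_id" for f in findings)

    def test_date_severity_folder_vs_file(self):
        tree = tree_of("d/2023-01-15 session/scan_2023-01-15.tif")
        dates = [
            f for f in check_obscure_and_external(tree, CFG)
            if f.suggestion and f.suggestion.get("pattern") == "date"
        ]
        sev = {f.paths[0]: f.severity for f in dates}
        assert sev["d/2023-01-15 session"] == "warning"
        assert sev["d/2023-01-15 session/scan_2023-01-15.tif"] == "info"


class TestPadding:
    def test_unpadded_sequence_flagged_with_width(self):
        tree = tree_of(*[f"d/stack/prefix-{i}.tif" for i in (1, 2, 10, 100, 1000)])
        (finding,) = check_padding(tree, CFG)
        assert finding.suggestion["width"] == 4

    def test_uniformly_padded_clean(self):
        tree = tree_of(*[f"d/stack/file_{i:04d}.tif" for i in range(1, 20)])
        assert check_padding(tree, CFG) == []

    def test_no_numeric_field_no_group(self):
        assert check_padding(tree_of("d/a.tif", "d/b.tif", "d/c.tif"), CFG) == []

    def test_groups_smaller_than_three_ignored(self):
        assert check_padding(tree_of("d/s-1.tif", "d/s-10.tif"), CFG) == []


class TestRootHygiene:
    def test_two_roots_flagged(self):
        findings = check_root_hygiene(tree_of("a/x.tif", "b/y.tif"), CFG)
        assert any(f.recommendation == "R2" for f in findings)

    def test_readme_and_checksums_satisfy(self):
        tree = tree_of("data/README", "data/md5-sums.txt", "data/sub/x.tif")
        assert check_root_hygiene(tree, CFG) == []

    def test_missing_checksums_only(self):
        tree = tree_of("data/README", "data/sub/x.tif")
        (finding,) = check_root_hygiene(tree, CFG)
        assert finding.recommendation == "R10"

    def test_empty_tree_reports_missing_top_level(self):
        findings = check_root_hygiene(read_manifest([]), CFG)
        assert {f.recommendation for f in findings} == {"R2", "R9a", "R10"}


class TestFormats:
    def test_proprietary_extension_advises_open_formats(self):
        (finding,) = check_formats(tree_of("d/scan.czi"), CFG)
        assert "OME-TIFF" in finding.message and finding.severity == "info"

    def test_ome_tiff_clean(self):
        assert check_formats(tree_of("d/image.ome.tiff"), CFG) == []

    def test_mixed_content_folder(self):
        exts = ["tif", "zip", "txt", "png", "mrc"]
        tree = tree_of(*[f"d/mix/f{i}.{exts[i % 5]}" for i in range(25)])
        findings = check_formats(tree, CFG)
        assert any("mixes" in f.message for f in findings)


class TestRunChecks:
    def test_unknown_check_id_lists_valid_ids(self):
        with pytest.raises(ValueError, match="valid ids"):
            run_checks(tree_of("d/x.tif"), CFG, enabled=["no_such_check"])

    def test_pure_and_order_independent(self):
        lines = [f"data/{LONG_TITLE}/x.tif", "data/readme.txt", "data/b/slice-1.tif",
                 "data/b/slice-2.tif", "data/b/slice-10.tif"]
        a = run_checks(read_manifest(lines), CFG)
        b = run_checks(read_manifest(list(reversed(lines))), CFG)
        assert [f.as_dict() for f in a] == [f.as_dict() for f in b]

    def test_sorted_by_path_then_check(self):
        findings = run_checks(tree_of(f"data/{LONG_TITLE}/x.tif"), CFG)
        keys = [(f.paths[0], f.check_id) for f in findings]
        assert keys == sorted(keys)

    def test_findings_reference_existing_paths(self, paper_tree):
        tree = paper_tree.tree
        known = tree.paths() | {"."}
        for f in run_checks(tree, CFG):
            assert set(f.paths) <= known

    def test_enabled_subset_only(self):
        findings = run_checks(
            tree_of(f"data/{LONG_TITLE}/x.tif"), CFG, enabled=["name_length"]
        )
        assert findings and all(f.check_id == "name_length" for f in findings)

    def test_every_registered_check_is_callable(self):
        tree = tree_of("data/readme.txt", "data/md5-sums.txt", "data/sub/x.tif")
        for check_id in CHECKS:
            run_checks(tree, CFG, enabled=[check_id])


class TestConfig:
    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            CheckConfig(max_name_length=0)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            CheckConfig.from_dict({"max_name_len": 10})

    def test_excluded_words_lowercased(self):
        cfg = CheckConfig(excluded_words={"Files", "DATA"})
        assert cfg.excluded_words == {"files", "data"}

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("max_name_length: 30\nexcluded_words: [files, misc]\n")
        cfg = CheckConfig.from_file(str(p))
        assert cfg.max_name_length == 30
        assert cfg.excluded_words == {"files", "misc"}
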