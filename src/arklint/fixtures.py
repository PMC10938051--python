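"""Test trees: the published pathological example and a labelled generator.

``build_paper_example`` reconstructs, from names printed in the article this
tool operationalises, the badly organised fictitious deposition used there
to motivate the recommendations: redundant single-child folders, an 88-char
folder name with spaces and a non-ASCII 'ö', obscure ten-digit identifiers,
a Treatment/Treatement spelling slip, a Tr1-323/Tr1323 separator variant, a
Topology/topology case variant, tomo/tomogram truncation, one treatment
folder breaking the structural pattern of its siblings, and unpadded slice
sequences.  Only a fraction of that figure's full listing is printed in the
article, so the remainder is filled with generic placeholders; placeholder
counts are not meaningful.

``generate_tree`` produces a compliant baseline tree from a fixed lowercase
vocabulary and injects labelled violations at seeded-random positions, so
linter recall can be measured against ground truth.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field as dc_field

from .tree_model import DatasetTree, read_manifest

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class ViolationSpec:
    """Request to inject ``count`` instances of one violation class."""

    check_id: str
    count: int = 1
    parameters: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class LabelledTree:
    """A tree plus ground-truth (path, check_id) labels."""

    tree: DatasetTree
    labels: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# The published worked example
# ---------------------------------------------------------------------------

LONG_TITLE_FOLDER = (
    "A U Thör et al - A very long relevant title that has most of the "
    "keywords in your paper"
)
DESCRIPTION_FOLDER = "A Folder with an overall description"
TREATMENT1_FOLDER = "0923480928 - Treatement Tr1-323 Tissue"
SEGMENTATION_FOLDER = "0923480928 Treatement Tr1-323 Segmentation"
TREATMENT2_FOLDER = "3738932082 - Treatment Tr2-323 Tissue"
TREATMENT3_FOLDER = "5647382910 - Treatment Tr3-323 Tissue"
WORKED_EXAMPLE_FILE = "0923480928_Treatement_Tr1323_Organelle1-topology1.zip"

#: the five components of the cleaned-up replacement path
REVISED_PATH_COMPONENTS = (
    "data",
    "brief_description",
    "treatment3_tissue",
    "segmentation",
    "organelle1_topology1.zip",
)
REVISED_PATH = "/".join(REVISED_PATH_COMPONENTS)

#: the seven issue classes annotated on the pathological example, mapped to
#: the checks (and near-duplicate variants) that detect them
ISSUE_CLASSES: dict[str, list[tuple[str, str | None]]] = {
    "long_names_spaces_nonascii_redundant_dirs": [
        ("name_length", None),
        ("characters", None),
        ("redundant_folders", None),
    ],
    "obscure_identifiers_inconsistent_spelling": [("obscure_and_external", None)],
    "hierarchy_inconsistency": [("cohort_structure", None)],
    "meaningless_identifiers": [("obscure_and_external", None)],
    "verbosity": [("path_repetition", None)],
    "spelling_variant": [
        ("sibling_near_duplicates", "typo"),
        ("sibling_near_duplicates", "separator"),
    ],
    "case_separator_inconsistency": [("sibling_near_duplicates", "case")],
}


def build_paper_example() -> LabelledTree:
    """Deterministic reconstruction of the published pathological dataset."""
    thor = f"data/{LONG_TITLE_FOLDER}"
    desc = f"{thor}/{DESCRIPTION_FOLDER}"
    t1 = f"{desc}/{TREATMENT1_FOLDER}"
    seg = f"{desc}/{SEGMENTATION_FOLDER}"
    t2 = f"{desc}/{TREATMENT2_FOLDER}"
    t3 = f"{desc}/{TREATMENT3_FOLDER}"
    zip1 = f"{t1}/{WORKED_EXAMPLE_FILE}"
    zip2 = f"{t2}/3738932082_Treatment_Tr2323_Organelle1-topology1.zip"
    zip3 = f"{t3}/5647382910_Treatment_Tr3323_Organelle1-Topology1.zip"

    lines: list[str] = [zip1, f"{seg}/{WORKED_EXAMPLE_FILE}", zip2, zip3]
    # 'Raw' stands in for the thousands of uncompressed TIFFs the article
    # says it refrains from listing; treatment 1's slices are unpadded
    lines += [f"{t1}/Raw/slice-{i}.tif" for i in range(1, 11)]
    lines += [f"{t2}/Raw/slice-{i:02d}.tif" for i in range(1, 5)]
    lines += [f"{t3}/Raw/slice-{i:02d}.tif" for i in range(1, 5)]
    # the extra child folder that breaks the treatment-folder pattern
    lines += [f"{t2}/Old Analysis/notes.txt"]
    # the truncation pair of sibling folders
    lines += [f"{desc}/tomo/t01.mrc", f"{desc}/tomogram/t02.mrc"]

    tree = read_manifest(lines)
    labels = [
        ("data", "redundant_folders"),
        (thor, "name_length"),
        (thor, "characters"),
        (thor, "obscure_and_external"),  # the 'et al' personal identifier
        (t1, "characters"),
        (t1, "obscure_and_external"),  # the meaningless '0923480928'
        (t2, "obscure_and_external"),  # the meaningless '3738932082'
        (t2, "cohort_structure"),
        (zip1, "name_length"),
        (zip1, "path_repetition"),
        (f"{t1}/Raw/slice-1.tif", "padding"),
        (t1, "sibling_near_duplicates"),  # Treatment vs Treatement; Tr1-323 vs Tr1323
        (zip3, "sibling_near_duplicates"),  # Organelle1-topology1 vs -Topology1
        (f"{desc}/tomo", "sibling_near_duplicates"),  # tomo vs tomogram
        ("data", "root_hygiene"),
    ]
    return LabelledTree(tree=tree, labels=labels)


def build_revised_example() -> DatasetTree:
    """The same dataset after applying the recommendations: lint-clean."""
    lines = ["data/readme.txt", "data/md5-sums.txt"]
    for t in ("treatment1_tissue", "treatment2_tissue", "treatment3_tissue"):
        base = f"data/brief_description/{t}"
        lines += [f"{base}/raw/image_{i:04d}.tif" for i in range(1, 5)]
        lines += [
            f"{base}/segmentation/organelle1_topology1.zip",
            f"{base}/segmentation/organelle2_topology1.zip",
        ]
    return read_manifest(lines)


# ---------------------------------------------------------------------------
# Seeded generator with labelled violations
# ---------------------------------------------------------------------------

_LEVEL_VOCAB = ("specimen", "condition", "section", "region", "field")
_ROOT_NAME = "microscopy"


def _clean_lines(breadth: int, depth: int, files_per_leaf: int) -> tuple[list[str], list[str], list[str]]:
    """Manifest lines for the compliant baseline, plus folder-path pools."""
    lines = [f"{_ROOT_NAME}/readme.txt", f"{_ROOT_NAME}/md5-sums.txt"]
    level1: list[str] = []
    leaves: list[str] = []

    def grow(parent: str, level: int) -> None:
        for j in range(1, breadth + 1):
            folder = f"{parent}/{_LEVEL_VOCAB[(level - 1) % len(_LEVEL_VOCAB)]}_{j:02d}"
            if level == 1:
                level1.append(folder)
            if level == depth:
                leaves.append(folder)
                for k in range(1, files_per_leaf + 1):
                    lines.append(f"{folder}/image_{k:04d}.tif")
            else:
                grow(folder, level + 1)

    grow(_ROOT_NAME, 1)
    return lines, level1, leaves


class _Injectors:
    """One method per supported violation class.

    Each call adds manifest lines for exactly one violation instance and
    returns the (path, check_id) label — the path equals the primary
    (first) subject path of the finding the linter will emit.
    """

    def __init__(self, rng: random.Random, lines: list[str], level1: list[str], leaves: list[str]):
        self.rng = rng
        self.lines = lines
        self.level1 = level1
        self.leaves = leaves
        self.counter = 0

    def _pick(self, pool: list[str]) -> str:
        return self.rng.choice(sorted(pool))

    def name_length(self, params: dict) -> tuple[str, str]:
        self.counter += 1
        folder = self._pick(self.leaves)
        over = int(params.get("length", 52))
        name = f"{'n' * over}_{self.counter:02d}.tif"
        self.lines.append(f"{folder}/{name}")
        return f"{folder}/{name}", "name_length"

    def path_length(self, params: dict) -> tuple[str, str]:
        self.counter += 1
        a = "p" * 148 + f"{self.counter:02d}"
        b = "q" * 138 + f"{self.counter:02d}"
        name = "f" * 60 + ".tif"
        self.lines.append(f"{_ROOT_NAME}/{a}/{b}/{name}")
        return f"{_ROOT_NAME}/{a}/{b}/{name}", "path_length"

    def characters(self, params: dict) -> tuple[str, str]:
        self.counter += 1
        folder = self._pick(self.leaves)
        name = f"bad name {self.counter:02d}.tif"
        self.lines.append(f"{folder}/{name}")
        return f"{folder}/{name}", "characters"

    def periods(self, params: dict) -> tuple[str, str]:
        self.counter += 1
        folder = self._pick(self.leaves)
        name = f"log.{self.counter:02d}.txt"
        self.lines.append(f"{folder}/{name}")
        return f"{folder}/{name}", "periods"

    def excluded_words(self, params: dict) -> tuple[str, str]:
        self.counter += 1
        folder = self._pick(self.level1)
        name = f"extra_files_{self.counter:02d}"
        self.lines.append(f"{folder}/{name}/")
        return f"{folder}/{name}", "excluded_words"

    def path_repetition(self, params: dict) -> tuple[str, str]:
        self.counter += 1
        folder = self._pick(self.level1)
        word = folder.rsplit("/", 1)[1].split("_")[0]
        name = f"{word}_notes_{self.counter:02d}.txt"
        self.lines.append(f"{folder}/{name}")
        return f"{folder}/{name}", "path_repetition"

    def padding(self, params: dict) -> tuple[str, str]:
        self.counter += 1
        folder = self._pick(self.leaves)
        prefix = f"frame{self.counter}-"
        for idx in (1, 2, 10):
            self.lines.append(f"{folder}/{prefix}{idx}.tif")
        return f"{folder}/{prefix}1.tif", "padding"

    def redundant_folders(self, params: dict) -> tuple[str, str]:
        self.counter += 1
        folder = self._pick(self.level1)
        outer = f"{folder}/outer_shell_{self.counter:02d}"
        self.lines.append(f"{outer}/inner_core_{self.counter:02d}/payload.txt")
        return outer, "redundant_folders"


def generate_tree(
    seed: int,
    base_shape: tuple[int, int, int] = (3, 2, 5),
    violations: list[ViolationSpec] | None = None,
) -> LabelledTree:
    """Seeded tree: compliant baseline plus requested labelled violations.

    ``base_shape`` is (breadth, folder depth below the root, files per leaf
    folder).  With no violations the tree passes every check under the
    default configuration; each :class:`ViolationSpec` adds exactly
    ``count`` labelled instances at seeded-random positions.  The root
    itself is never touched, so root-hygiene results stay orthogonal.
    """
    breadth, depth, files_per_leaf = base_shape
    if min(breadth, depth, files_per_leaf) < 1:
        raise ValueError("shape parameters must be positive")
    if depth > 3:
        raise ValueError(
            "folder depth above 3 cannot produce a clean baseline under the "
            "default depth limit of 4 levels including the root"
        )
    if breadth > 99 or files_per_leaf > 9999:
        raise ValueError("shape too large for the fixed-width clean naming scheme")

    lines, level1, leaves = _clean_lines(breadth, depth, files_per_leaf)
    labels: list[tuple[str, str]] = []
    rng = random.Random(seed)
    inj = _Injectors(rng, lines, level1, leaves)
    for spec in violations or []:
        method = getattr(inj, spec.check_id, None)
        if method is None or spec.check_id.startswith("_"):
            supported = [m for m in vars(_Injectors) if not m.startswith("_")]
            raise ValueError(
                f"cannot inject violations for {spec.check_id!r}; "
                f"supported: {sorted(supported)}"
            )
        for _ in range(spec.count):
            labels.append(method(spec.parameters))
    return LabelledTree(tree=read_manifest(lines), labels=labels)


def materialise(tree: DatasetTree, dest_dir: str) -> None:
    """Write a tree to disk with small deterministic per-file contents."""
    for path, entry, _depth in tree.walk():
        full = os.path.join(dest_dir, *path.split("/"))
        if entry.is_folder:
            os.makedirs(full, exist_ok=True)
        else:
            os.makedirs(os.path.dirname(full), exist_ok=True)
            with open(full, "wb") as fh:
                fh.write(f"synthetic placeholder content for {path}\n".encode())
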