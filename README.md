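# arklint

A linter and mechanical fix planner for the file/folder organisation of
bioimaging datasets being prepared for public archival (EMPIAR, BioImage
Archive, BioStudies and similar).

## The problem

Bioimaging depositions are often huge trees of files whose *organisation* —
not just metadata — decides how usable they are. Recurring defects fall
into four families:

- **verbosity/redundancy** — folders that contain only a single folder,
  names repeating identifiers already present in an ancestor folder;
- **ambiguity** — spaces and non-ASCII characters, near-identical
  identifiers (`Tr1-323` vs `Tr1323`);
- **inconsistency** — spelling slips between related names (`Treatment` vs
  `Treatement`), case variants (`Topology` vs `topology`), one cohort
  member whose sub-structure breaks its siblings' pattern;
- **obscurity** — meaningless numeric identifiers (`0923480928`),
  references to external artefacts ("Figure 5"), dates in folder names.

`arklint` detects these, plus hard limits that legacy software imposes
(name length ≤ 50 characters, path length ≤ 320 characters, ≤ 4 folder
levels, ≤ 10,000 files per folder), checks root hygiene (one top-level
folder with a README and a checksum manifest), infers zero-padding defects
in slice sequences, and classifies proprietary vs open image formats.

It then plans *mechanical* repairs: collapsing redundant single-child
folder chains, de-duplicating repeated path tokens, normalising names to
lowercase/underscore/hyphen convention (`'A Folder with an overall
description'` → `a_folder_with_an_overall_description`), splitting
oversized folders into `child00…childNN`, and zero-padding numeric
sequences so lexicographic order equals slice order. Choosing a
*meaningful* replacement name is human judgement; the report says where
that is still needed.

Key algorithmic pieces: an unrestricted Damerau–Levenshtein distance
(Lowrance–Wagner) for near-duplicate detection; structural "name
skeletons" (digit runs → `#`, letter runs → `a`) so sequential siblings
(`child00`/`child01`) never count as typos while a cohort member with an
extra child level is caught; and an injective, deepest-first rename plan
that is idempotent by construction.

## Worked example

The package ships a reconstruction of a pathologically organised
deposition (`arklint fixture paper`), including paths such as

```
data/A U Thör et al - A very long relevant title that has most of the keywords in your paper/
  A Folder with an overall description/
    0923480928 - Treatement Tr1-323 Tissue/
      0923480928_Treatement_Tr1323_Organelle1-topology1.zip
      Raw/slice-1.tif … slice-10.tif
    ...
```

Linting it:

```sh
arklint fixture paper > manifest.txt
arklint lint --manifest manifest.txt
```

prints (abridged):

```
arklint 0.1.0 — 25 files, 13 folders, max depth 6, longest path 226 chars
59 issues found (15 info, 44 warning).

[characters] (R6b) — 22 finding(s)
[cohort_structure] (R7a) — 1 finding(s)
[depth] (R3b) — 4 finding(s)
[name_length] (R3a) — 5 finding(s)
[obscure_and_external] (R7b) — 9 finding(s)
[padding] (R7e) — 1 finding(s)
[path_repetition] (R7d) — 8 finding(s)
[redundant_folders] (R3c) — 1 finding(s)
[root_hygiene] (R9a) — 2 finding(s)
[sibling_near_duplicates] (R7a) — 6 finding(s)
```

Each group lists the offending paths and a machine-readable suggestion —
e.g. the `padding` finding on `Raw/slice-1.tif…slice-10.tif` suggests
width 2, and `redundant_folders` points at the `data → A U Thör et al… →
A Folder with an overall description` single-child chain. A mechanical
rename plan (`arklint suggest`) produces 36 steps that collapse the chain
and normalise every name, e.g.

```
data/…/0923480928 - Treatement Tr1-323 Tissue/0923480928_Treatement_Tr1323_Organelle1-topology1.zip
  -> data/a_folder_with_an_overall_description/0923480928-treatement_tr1-323_tissue/tr1323_organelle1-topology1.zip
```

after which the character/period/repetition checks are clean and only the
defects needing human judgement (obscure identifiers, spelling variants)
remain. `arklint apply plan.json --root DIR` executes a plan
(dry run by default), and `arklint checksum write|verify` maintains
coreutils-compatible digest manifests.

A compliant tree lints clean: the cleaned-up counterpart of the example
above (`data/brief_description/treatment3_tissue/segmentation/…`, a
78-character path) yields `0 issues found.` and exit code 0.

## Configuration

Every numeric limit and vocabulary lives in `CheckConfig` and can be set
from a YAML/JSON file (`--config`) or per-run flags
(`--max-name-length`, `--max-depth`, …). Severities are advisory: hard
limits report as warnings, stylistic points as info, and `lint` exits 0
unless `--fail-on info|warning|error` is given.
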