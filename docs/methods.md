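# Methods

This note records how `arklint` models dataset organisation, the rules and
parameters it applies, the design decisions taken where more than one
reasonable convention exists, and what the synthetic fixtures do and do not
demonstrate.

## The tree model

A dataset is a forest of named entries (files and folders). Ingest —
whether from a filesystem walk or from a plain-text path manifest — never
alters a single byte of any name: defects must reach the linter verbatim,
so Unicode names, spaces and control-ish characters are findings, never
ingest errors. Only manifest *syntax* errors (absolute paths, empty
components, a path declared both file and folder) are rejected, with line
numbers. Child order is fixed to byte-wise lexicographic so reports and
plans are reproducible; symbolic links are recorded as files and never
followed; unreadable subfolders become warnings and the walk continues.

**Depth convention.** The single top-level folder is level 1, so a file
directly inside it sits at depth 2. The depth check flags folders at a
level greater than `max_depth` (default 4, i.e. three folder levels below
the top-level folder). Whether the root counts is itself a convention, so
it is exposed as `depth_counts_root`; with it off, limits apply to levels
below the root. Path length is measured in characters of the relative
POSIX path with no leading slash.

## Checks

All checks are pure functions `(tree, config) -> findings`, run from a
registry and sorted by `(path, check_id)`; identical inputs give identical
output. Severity is advisory by design: these are recommendations, not a
standard, so hard limits (path length, forbidden characters, files per
folder) are warnings, stylistic points (letter case, filler words) are
info, and nothing is an error by default. `lint` only fails the process
when asked (`--fail-on`).

Parameters that matter (all in `CheckConfig`, all inclusive at the stated
bound — a 50-character name passes, 51 fails):

| parameter | default | meaning |
|---|---|---|
| `max_name_length` | 50 chars | component-name limit users can still type reliably |
| `max_path_length` | 320 chars | legacy input-path limit (IMOD-era software) |
| `max_depth` | 4 levels | folder nesting, counting the root as level 1 |
| `max_files_per_folder` | 10,000 | the classic ext2 soft limit; beyond it a split plan is suggested |
| `min_digit_run` | 6 | digit runs at least this long count as obscure identifiers |
| `sibling_distance_threshold` | 1 | edit distance treated as a spelling slip |
| `repetition_min_token_len` | 3 | shortest token the repetition check flags, so connectives never fire |
| `mixed_content_min_files` / `_max_classes` | 20 / 3 | folder size and format spread that trigger the mixed-content warning |

Notable rule mechanics:

- **Characters.** One finding per distinct offending character per name
  (space, the specifically called-out `& ! ?`, non-ASCII with its
  codepoint, other non-portable characters), plus a single info-level case
  finding when uppercase letters appear. The portable set is POSIX's
  `A–Z a–z 0–9 . _ -`.
- **Periods.** A file may carry one trailing extension or a whitelisted
  multi-part extension (`.tar.gz`, `.ome.tiff`, `.ome.tf2`, `.ome.tf8`,
  `.ome.btf`); any other period, and any period in a folder name, is
  flagged.
- **Near-duplicates.** Tokens (hyphens kept, since hyphens mark keywords
  like `covid-19`) are compared tree-wide, and full sibling names within
  each folder. A pair is flagged as a case variant, separator variant
  (equal after removing separators), truncation (one all-alphabetic name a
  proper prefix of the other, catching `tomo`/`tomogram`), or spelling
  slip (Damerau–Levenshtein distance within the threshold). Pairs that
  differ only inside digit runs are exempt — `child00`/`child01` and
  `slice-0001`/`slice-0002` are sequences, not typos. Tokens shorter than
  three characters are ignored (short connectives produced only noise).
  The pairwise rules are skipped above 400 names/tokens to keep the check
  linear-ish on huge flat folders; the grouping rules still apply.
- **Edit distance.** The *unrestricted* Damerau–Levenshtein distance
  (Lowrance–Wagner) is implemented rather than the common restricted
  (OSA) variant: the restricted form violates the triangle inequality,
  which matters once distances feed a consistency heuristic, and the
  difference is observable on strings as short as `ca`/`ac`/`abc`. The
  test suite checks it exhaustively against an independent breadth-first
  edit-search oracle for all pairs of length ≤ 4 over a 3-letter alphabet.
- **Cohorts.** Sibling folders sharing a non-numeric token of ≥ 3
  characters form a cohort. With at least three members and a strict
  majority sharing a *shape signature* — the multiset of (kind, name
  skeleton) of direct children plus subtree depth, where a skeleton maps
  digit runs to `#` and letter runs to `a` — members off the majority are
  flagged at info severity. The skeleton abstraction is deliberate: a
  cohort whose child names carry a spelling slip still has one shape, so
  an extra child level is caught without every member looking unique.
  This is the least certain check; it ships enabled but info-level.
- **Padding.** Sibling files whose stem ends in a decimal run and share
  the remaining (prefix, extension) form a group once three members
  exist. Inconsistent field widths — or a uniform width smaller than the
  digit count of the maximum index — are flagged, with the correct width
  (digits of the maximum index) in the suggestion.
- **Obscure/external names.** Digit runs of ≥ `min_digit_run` (runs that
  parse as plausible dates are reported as dates instead, with year
  1900–2099, month 01–12, day 01–31); dates (warning in folder names,
  info in file names — mass-renaming folders is the painful case);
  figure references (`fig`/`figure`, word-bounded so "configuration"
  never matches); and personal identifiers. Personal-name detection
  without a name dictionary is not feasible, so only a configurable
  blocklist plus an "et al" token-sequence heuristic is provided.
- **Excluded words.** `files`, `data`, `images` by default, whole-token
  match only. The top-level folder is exempt (a generic `data/` root is
  conventional); the exemption is configurable.
- **Root hygiene.** Exactly one top-level folder, containing a README
  (`readme`, `readme.txt`, `readme.md`, case-insensitive) and a checksum
  or parity file (`md5*`, `sha256*`, `sha512*`, `*.par2`, `*sums.txt`,
  `*hashes.txt`). PAR2 files are detected by name only, never parsed.
- **Formats.** Extension-based classification only — file contents are
  never read. Proprietary extensions (`.czi`, `.lif`, `.nd2`, …) get an
  info finding recommending OME-TIFF/OME-NGFF; folders mixing ≥ 20 files
  across > 3 format classes get a grouping warning.

## Fix planning

`build_rename_plan` composes three mechanical passes: collapse of
single-folder chains (each maximal chain is replaced by the first folder
that actually holds content; the top-level folder is never collapsed),
per-component token de-duplication against ancestor names (short numeric
tokens such as `1` survive — they are indices, not repetition — and a
component is never emptied: if everything repeats, the last token stays),
and name normalisation (NFKD transliteration `ö → o`, lowercase, spaces to
underscores, forbidden characters dropped, stem periods to underscores,
separator runs collapsed with hyphens winning over underscores, the
final or whitelisted multi-part extension preserved for files).

Collisions are resolved deterministically: the entry with the byte-wise
larger source path gets a `-2` (then `-3`, …) suffix, placed before the
extension and using the hyphen as the keyword position. This rule is
applied uniformly, so when a dirty name normalises onto an existing clean
sibling, whichever has the larger source path moves — surprising in the
individual case but reproducible and order-free.

The plan maps every entry whose full path changes, ordered deepest-first
so children move before parents; disk application creates target parents
as needed, merges into already-created directories, prunes empty husks
left by chain collapse, and appends executed moves to a JSON-lines
journal. Dry run is the default.

Guarantees, and their limits: plans are injective and idempotent
(property-tested across generated trees), and after a plan the
character, period and path-repetition checks are clean. Over-long names
are *not* truncated, obscure identifiers are *not* invented away, and
spelling variants between distinct names (`treatment`/`treatement`) are
not merged — picking the right survivor is semantics, and the lint report
marks where that judgement is still needed. Split plans name children
`child00…` with a width that grows with the child count (minimum two
digits) and assign contiguous index ranges of at most the cap; padding
plans use the digit count of the maximum index and refuse ambiguous
sequences (duplicate indices).

## Integrity

Checksum manifests use the coreutils text format (`<digest>␣␣<path>`,
UTF-8, LF), sorted by path, with the manifest file excluded from its own
entries. Parsing accepts one or two separating spaces and the `*`
binary-mode marker, and infers the algorithm (md5/sha256/sha512) from the
digest length. Hashing streams in 1 MiB blocks so memory use is flat
regardless of image size. Verification reports per-entry
ok/mismatch/missing plus untracked files on disk; it passes iff nothing is
mismatched or missing (untracked files are advisory).

## Synthetic fixtures and what the tests show

`build_paper_example` reconstructs the motivating pathological deposition
from the names printed in the article text this tool operationalises; the
thousands of raw TIFFs that figure elides are stood in for by ten
deliberately unpadded placeholder slices, so placeholder counts carry no
meaning. Ground-truth labels cover all seven annotated issue classes.

`generate_tree(seed, (breadth, depth, files_per_leaf), violations)` builds
a compliant baseline from a fixed lowercase vocabulary
(`specimen`/`condition`/`section`/`region`/`field` per level, zero-padded
indices, `image_0001.tif` leaves, a root with `readme.txt` and
`md5-sums.txt`). The default shape (3, 2, 5) — 13 folders, 47 files — is
deliberately small so that 100-seed property runs stay cheap. With no
violations the tree yields zero findings (the false-positive guard);
each `ViolationSpec` injects exactly `count` labelled instances of one
class at seeded-random positions, and for the deterministic classes
(name/path length, character set, periods, excluded words, repetition,
padding, single-child chains) the linter's findings match the labels
exactly (the recall guard). Injections can knock collateral findings of
*other* classes loose (an injected file changes its folder's cohort
shape, for instance), which is correct linter behaviour; recall is
therefore asserted per class.

What this does **not** show about real data: real depositions have
heterogeneous vocabularies, deeper and more irregular shapes, and defect
densities far from these fixtures; the near-duplicate and cohort
heuristics in particular trade recall for precision and were tuned on the
printed example, not on archive-scale corpora. File *contents* are never
inspected, so format findings are only as good as extension conventions.

## Numerical and degenerate-input choices

- Empty trees lint without crashing: root-hygiene findings attach to the
  placeholder path `.`, the only case where a finding path is not a tree
  path.
- An empty manifest is an empty tree, not an error.
- A name that normalises to nothing (e.g. `???`) raises, and the rename
  planner falls back to `unnamed` plus the original extension, relying on
  collision suffixes for uniqueness.
- Date plausibility is deliberately loose (no month-length table): the
  cost of a false date is only that an 8-digit run is reported as a date
  rather than an obscure identifier.
- The `stats` extension histogram uses the plain last suffix; multi-part
  extension awareness lives only where the whitelist is configured
  (periods/formats checks and normalisation).
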