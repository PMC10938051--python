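"""Checksum manifests: write, parse and verify (coreutils-compatible).

A dataset prepared for archival should ship a digest for every data file so
users can verify nothing was corrupted in transfer.  Manifests use the
``md5sum``/``sha512sum`` text format — ``<hex digest>  <relative path>`` —
so standard tools can consume them directly.  PAR2 parity files are
recognised by name for the hygiene check but never parsed or generated.
"""

from __future__ import annotations

import fnmatch
import hashlib
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .tree_model import DatasetTree

ALGORITHMS = {"md5": 32, "sha256": 64, "sha512": 128}

# streaming read size: memory use stays flat however large the image files are
_BLOCK_SIZE = 1 << 20

DEFAULT_CHECKSUM_PATTERNS = (
    "md5*",
    "sha256*",
    "sha512*",
    "*.par2",
    "*sums.txt",
    "*hashes.txt",
)


class ManifestParseError(ValueError):
    def __init__(self, message: str, line_no: int):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


@dataclass
class ChecksumManifest:
    algorithm: str
    entries: list[tuple[str, str]] = field(default_factory=list)  # (path, hex digest)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unsupported algorithm {self.algorithm!r}; choose from {sorted(ALGORITHMS)}"
            )
        want = ALGORITHMS[self.algorithm]
        seen = set()
        for path, digest in self.entries:
            if len(digest) != want or any(c not in "0123456789abcdef" for c in digest):
                raise ValueError(
                    f"digest for {path!r} is not a {want}-char lowercase hex string"
                )
            if path.startswith("/"):
                raise ValueError(f"manifest paths must be relative: {path!r}")
            if path in seen:
                raise ValueError(f"duplicate manifest path {path!r}")
            seen.add(path)

    def to_text(self) -> str:
        return "".join(f"{digest}  {path}\n" for path, digest in self.entries)


@dataclass
class VerificationReport:
    ok: list[str] = field(default_factory=list)
    mismatch: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    untracked: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.mismatch and not self.missing


def hash_file(path: str, algorithm: str) -> str:
    h = hashlib.new(algorithm)
    with open(path, "rb") as fh:
        while True:
            block = fh.read(_BLOCK_SIZE)
            if not block:
                break
            h.update(block)
    return h.hexdigest()


def _iter_regular_files(root: str) -> Iterable[str]:
    """Relative POSIX paths of regular files under ``root``, sorted."""
    out = []
    for dirpath, dirnames, filenames in os.walk(root):
        dirnames.sort()
        for name in sorted(filenames):
            full = os.path.join(dirpath, name)
            if os.path.islink(full) or not os.path.isfile(full):
                continue
            rel = os.path.relpath(full, root)
            out.append(rel.replace(os.sep, "/"))
    return sorted(out)


def write_manifest(
    root: str,
    algorithm: str = "md5",
    manifest_name: Optional[str] = None,
) -> tuple[ChecksumManifest, str, list[str]]:
    """Hash every regular file under ``root`` and write the manifest there.

    Returns ``(manifest, manifest_path, warnings)``.  The manifest file
    itself is excluded from its own entries; unreadable files are skipped
    with a warning.  Entries are sorted by path; the file format is the
    coreutils two-space style, UTF-8, LF line endings.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unsupported algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}"
        )
    manifest_name = manifest_name or f"{algorithm}-sums.txt"
    warnings: list[str] = []
    entries: list[tuple[str, str]] = []
    for rel in _iter_regular_files(root):
        if rel == manifest_name:
            continue
        try:
            digest = hash_file(os.path.join(root, *rel.split("/")), algorithm)
        except OSError as exc:
            warnings.append(f"unreadable file skipped: {rel!r} ({exc})")
            continue
        entries.append((rel, digest))
    manifest = ChecksumManifest(algorithm=algorithm, entries=entries)
    manifest_path = os.path.join(root, manifest_name)
    with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(manifest.to_text())
    return manifest, manifest_path, warnings


def parse_manifest(text: str, algorithm: Optional[str] = None) -> ChecksumManifest:
    """Parse coreutils-style manifest text.

    Accepts one or two spaces between digest and path, and the ``*`` marker
    that ``md5sum`` uses for binary mode.  When ``algorithm`` is not given
    it is inferred from the digest length of the first entry.
    """
    entries: list[tuple[str, str]] = []
    inferred = algorithm
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        digest, sep, rest = line.partition(" ")
        if not sep or not rest:
            raise ManifestParseError("expected '<digest> <path>'", line_no)
        digest = digest.lower()
        if rest.startswith(" "):
            rest = rest[1:]
        if rest.startswith("*"):
            rest = rest[1:]
        if not rest:
            raise ManifestParseError("missing path", line_no)
        if inferred is None:
            for algo, length in ALGORITHMS.items():
                if len(digest) == length:
                    inferred = algo
                    break
            else:
                raise ManifestParseError(
                    f"digest length {len(digest)} matches no supported algorithm",
                    line_no,
                )
        if len(digest) != ALGORITHMS[inferred] or any(
            c not in "0123456789abcdef" for c in digest
        ):
            raise ManifestParseError(
                f"malformed {inferred} digest {digest!r}", line_no
            )
        entries.append((rest, digest))
    if inferred is None:
        inferred = algorithm or "md5"
    return ChecksumManifest(algorithm=inferred, entries=entries)


def read_manifest_file(path: str, algorithm: Optional[str] = None) -> ChecksumManifest:
    with open(path, encoding="utf-8") as fh:
        return parse_manifest(fh.read(), algorithm=algorithm)


def verify_manifest(
    root: str,
    manifest: ChecksumManifest,
    manifest_name: Optional[str] = None,
) -> VerificationReport:
    """Check every manifest entry against the files under ``root``.

    Files on disk that the manifest does not mention are reported as
    untracked (the manifest file itself does not count).  The report passes
    iff there are no mismatches and no missing files.
    """
    report = VerificationReport()
    listed = {path for path, _d in manifest.entries}
    for path, digest in manifest.entries:
        full = os.path.join(root, *path.split("/"))
        if not os.path.isfile(full):
            report.missing.append(path)
            continue
        actual = hash_file(full, manifest.algorithm)
        if actual == digest:
            report.ok.append(path)
        else:
            report.mismatch.append(path)
    skip = {manifest_name} if manifest_name else {f"{manifest.algorithm}-sums.txt"}
    for rel in _iter_regular_files(root):
        if rel not in listed and rel not in skip:
            report.untracked.append(rel)
    return report


def detect_checksum_files(
    tree: DatasetTree, patterns: Iterable[str] = DEFAULT_CHECKSUM_PATTERNS
) -> list[str]:
    """Paths of entries whose names look like checksum/parity files."""
    pats = [p.lower() for p in patterns]
    out = []
    for path, entry, _depth in tree.walk():
        if entry.is_file and any(
            fnmatch.fnmatchcase(entry.name.lower(), p) for p in pats
        ):
            out.append(path)
    return sorted(out)
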