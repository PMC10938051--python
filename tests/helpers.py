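"""Shared test helpers: tree construction shorthand and independent oracles."""

from __future__ import annotations

from collections import deque

from arklint.tree_model import DatasetTree, read_manifest


def tree_of(*paths: str) -> DatasetTree:
    """Build a tree from manifest-style path strings."""
    return read_manifest(list(paths))


def bfs_edit_distance(a: str, b: str) -> int:
    """Independent Damerau–Levenshtein oracle: breadth-first search over
    single edit operations (substitute, insert, delete, transpose-adjacent).

    Intermediate strings are capped at max(len(a), len(b)) + 2 characters;
    growing further than that cannot lie on a unit-cost shortest path for
    the string sizes exercised here.
    """
    if a == b:
        return 0
    alphabet = sorted(set(a) | set(b)) or ["a"]
    cap = max(len(a), len(b)) + 2
    dist = {a: 0}
    queue = deque([a])
    while queue:
        s = queue.popleft()
        d = dist[s] + 1
        neighbours = set()
        n = len(s)
        for i in range(n):
            neighbours.add(s[:i] + s[i + 1 :])  # delete
            for c in alphabet:
                neighbours.add(s[:i] + c + s[i + 1 :])  # substitute
        if n + 1 <= cap:
            for i in range(n + 1):
                for c in alphabet:
                    neighbours.add(s[:i] + c + s[i:])  # insert
        for i in range(n - 1):
            neighbours.add(s[:i] + s[i + 1] + s[i] + s[i + 2 :])  # transpose
        for t in neighbours:
            if t == b:
                return d
            if len(t) <= cap and t not in dist:
                dist[t] = d
                queue.append(t)
    raise AssertionError("unreachable: edit graph is connected")


def brute_force_stats(paths: list[str]) -> dict:
    """Recompute tree statistics directly from a path list (files only).

    Folder paths are implied by file ancestors; returns the same quantities
    as ``tree_stats`` for cross-checking.
    """
    files = set(paths)
    folders: set[str] = set()
    for p in files:
        parts = p.split("/")
        for i in range(1, len(parts)):
            folders.add("/".join(parts[:i]))
    all_paths = files | folders
    per_folder_files: dict[str, int] = {}
    for f in files:
        parent = "/".join(f.split("/")[:-1])
        if parent:  # top-level file roots have no containing folder
            per_folder_files[parent] = per_folder_files.get(parent, 0) + 1
    exts: dict[str, int] = {}
    for f in files:
        name = f.split("/")[-1]
        idx = name.rfind(".")
        ext = name[idx:].lower() if 0 < idx < len(name) - 1 else ""
        exts[ext] = exts.get(ext, 0) + 1
    return {
        "n_files": len(files),
        "n_folders": len(folders),
        "max_depth": max((p.count("/") + 1 for p in all_paths), default=0),
        "max_files_in_one_folder": max(per_folder_files.values(), default=0),
        "max_path_length": max((len(p) for p in all_paths), default=0),
        "max_name_length": max((len(p.split("/")[-1]) for p in all_paths), default=0),
        "extension_histogram": exts,
    }
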