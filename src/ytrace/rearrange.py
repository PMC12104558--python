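"""Signed-permutation rearrangement core and ancestral-insertion parsimony.

The central quantity is the signed inversion (reversal) distance between two
arrangements of oriented synteny blocks: the minimum number of operations
that reverse a contiguous run of blocks and flip their orientations.  It is
computed exactly with Hannenhalli-Pevzner theory on the extended breakpoint
graph,

    d = n + 1 - c + h + f,

where ``n`` is the number of blocks, ``c`` the number of breakpoint-graph
cycles, ``h`` the number of hurdles (unoriented components that occupy a
contiguous arc on the circle of unoriented-component endpoints) and ``f`` a
fortress correction (1 when the hurdle count is odd and every hurdle is a
superhurdle).  Arrangements are linear; they are capped with fixed sentinels
that never move.

A breadth-first-search oracle over the reversal Cayley graph is provided for
verification at small n; it is exact by construction and shares no code with
the breakpoint-graph route.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SignedBlock",
    "AncestralConfig",
    "ScenarioTable",
    "parse_block",
    "parse_arrangement",
    "format_arrangement",
    "apply_inversion",
    "inversion_distance",
    "bfs_distance_oracle",
    "bfs_all_distances",
    "sorting_scenario",
    "enumerate_ancestral_configs",
    "score_scenarios",
    "load_xq_arrangements",
]


@dataclass(frozen=True)
class SignedBlock:
    """An oriented synteny block: a label and a sign ('+' or '-')."""

    id: str
    sign: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("block id must be nonempty")
        if self.sign not in "+-":
            raise ValueError(f"bad sign {self.sign!r}")

    def flipped(self) -> "SignedBlock":
        return SignedBlock(self.id, "-" if self.sign == "+" else "+")

    def __str__(self) -> str:
        return f"{self.id}{self.sign}"


Arrangement = tuple[SignedBlock, ...]


def parse_block(token: str) -> SignedBlock:
    token = token.strip()
    if token[-1] not in "+-":
        raise ValueError(f"block token {token!r} must end in + or -")
    return SignedBlock(token[:-1], token[-1])


def parse_arrangement(text: str | Iterable[str]) -> Arrangement:
    """Parse 'SB1+ SB6- SB5- ...' (or an iterable of tokens)."""
    tokens = text.split() if isinstance(text, str) else list(text)
    arr = tuple(parse_block(t) for t in tokens)
    ids = [b.id for b in arr]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate block ids in arrangement: {ids}")
    return arr


def format_arrangement(arr: Arrangement) -> str:
    return " ".join(str(b) for b in arr)


def apply_inversion(arr: Sequence[SignedBlock], i: int, j: int) -> Arrangement:
    """Reverse blocks at positions [i, j] inclusive and flip their signs."""
    if not 0 <= i <= j < len(arr):
        raise IndexError(f"inversion ({i},{j}) outside arrangement of {len(arr)}")
    mid = tuple(b.flipped() for b in reversed(arr[i : j + 1]))
    return tuple(arr[:i]) + mid + tuple(arr[j + 1 :])


def exclude_blocks(arr: Sequence[SignedBlock], ids: Iterable[str]) -> Arrangement:
    drop = set(ids)
    return tuple(b for b in arr if b.id not in drop)


# ---------------------------------------------------------------------------
# Signed permutation encoding
# ---------------------------------------------------------------------------

def _to_signed_perm(a: Sequence[SignedBlock], b: Sequence[SignedBlock]) -> tuple[int, ...]:
    """Relabel so that ``b`` is the identity +1..+n; return ``a`` as a signed
    permutation.  Raises if the block id sets differ."""
    ids_a = {blk.id for blk in a}
    ids_b = {blk.id for blk in b}
    if ids_a != ids_b or len(a) != len(b):
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise ValueError(f"block sets differ; symmetric difference: {diff}")
    rank = {blk.id: i + 1 for i, blk in enumerate(b)}
    sign_b = {blk.id: blk.sign for blk in b}
    return tuple(
        rank[blk.id] if blk.sign == sign_b[blk.id] else -rank[blk.id] for blk in a
    )


# ---------------------------------------------------------------------------
# Hannenhalli-Pevzner distance
# ---------------------------------------------------------------------------

def _hp_components(perm: Sequence[int]):
    """Breakpoint-graph bookkeeping for a signed permutation vs identity.

    Returns (n, n_cycles, components) where components is a list of
    (is_oriented, [gray edge position pairs]) over nontrivial gray edges.
    """
    n = len(perm)
    u = [0]
    for v in perm:
        u.extend((2 * v - 1, 2 * v) if v > 0 else (-2 * v, -2 * v - 1))
    u.append(2 * n + 1)
    pos = [0] * (2 * n + 2)
    for i, val in enumerate(u):
        pos[val] = i

    # black matching: gap i joins u[2i], u[2i+1]
    black = {}
    for i in range(n + 1):
        x, y = u[2 * i], u[2 * i + 1]
        black[x] = y
        black[y] = x

    # cycle count (alternating black/gray walk)
    seen = [False] * (2 * n + 2)
    n_cycles = 0
    for start in range(2 * n + 2):
        if seen[start]:
            continue
        n_cycles += 1
        v = start
        while True:
            seen[v] = True
            w = black[v]
            seen[w] = True
            v = w ^ 1  # gray partner: 2i <-> 2i+1
            if v == start:
                break

    # nontrivial gray edges as sorted position pairs
    edges = []
    for i in range(n + 1):
        p, q = pos[2 * i], pos[2 * i + 1]
        if p > q:
            p, q = q, p
        if q - p > 1:  # q == p+1 is an adjacency (trivial 2-cycle)
            edges.append((p, q))

    # union-find over interleaving gray edges
    parent = list(range(len(edges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (p1, q1) in enumerate(edges):
        for j in range(i + 1, len(edges)):
            p2, q2 = edges[j]
            if (p1 < p2 < q1 < q2) or (p2 < p1 < q2 < q1):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    comp_edges: dict[int, list[tuple[int, int]]] = {}
    for i in range(len(edges)):
        comp_edges.setdefault(find(i), []).append(edges[i])
    components = []
    for es in comp_edges.values():
        oriented = any((p + q) % 2 == 0 for p, q in es)
        components.append((oriented, es))
    return n, n_cycles, components


def _hurdle_ids(labels: list[int], comp_ids: list[int]) -> set[int]:
    """Components whose occurrences form one circularly-consecutive run."""
    hurdles = set()
    m = len(labels)
    for cid in comp_ids:
        idxs = [i for i, l in enumerate(labels) if l == cid]
        k = len(idxs)
        runs_linear = sum(
            1 for a, b in zip(idxs, idxs[1:]) if b != a + 1
        ) + 1
        # circular: a block may wrap around the ends
        wraps = idxs[0] == 0 and idxs[-1] == m - 1 and k < m
        n_runs = runs_linear - (1 if wraps and runs_linear > 1 else 0)
        if n_runs == 1 or k == m:
            hurdles.add(cid)
    return hurdles


def _hurdles_and_fortress(components) -> tuple[int, int]:
    unoriented = [es for oriented, es in components if not oriented]
    if not unoriented:
        return 0, 0
    # circular sequence of unoriented-component ids, in position order
    marks: list[tuple[int, int]] = []
    for cid, es in enumerate(unoriented):
        for p, q in es:
            marks.append((p, cid))
            marks.append((q, cid))
    marks.sort()
    labels = [cid for _, cid in marks]
    comp_ids = list(range(len(unoriented)))
    hurdles = _hurdle_ids(labels, comp_ids)
    h = len(hurdles)
    if h == 0:
        return 0, 0
    if h % 2 == 0 or h < 3:
        return h, 0
    # fortress iff every hurdle is a superhurdle: deleting it promotes a
    # previously non-hurdle unoriented component to hurdle status
    all_super = True
    for hid in hurdles:
        reduced = [l for l in labels if l != hid]
        remaining = [c for c in comp_ids if c != hid]
        new_hurdles = _hurdle_ids(reduced, remaining)
        if not (new_hurdles - hurdles):
            all_super = False
            break
    return h, 1 if all_super else 0


def hp_distance(perm: Sequence[int]) -> int:
    """Signed inversion distance of ``perm`` from the identity permutation."""
    if not perm:
        return 0
    n, c, components = _hp_components(perm)
    h, f = _hurdles_and_fortress(components)
    return n + 1 - c + h + f


def inversion_distance(a: Sequence[SignedBlock], b: Sequence[SignedBlock]) -> int:
    """Minimum number of signed inversions transforming ``a`` into ``b``."""
    return hp_distance(_to_signed_perm(a, b))


def breakpoint_count(a: Sequence[SignedBlock], b: Sequence[SignedBlock]) -> int:
    """Number of breakpoints of ``a`` relative to ``b`` (with sentinels)."""
    perm = _to_signed_perm(a, b)
    ext = (0,) + perm + (len(perm) + 1,)
    return sum(1 for x, y in zip(ext, ext[1:]) if y - x != 1)


# ---------------------------------------------------------------------------
# BFS oracle
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def bfs_all_distances(n: int) -> Mapping[tuple[int, ...], int]:
    """Exact reversal distances from the identity to every signed permutation
    of size ``n``, by breadth-first search over the reversal Cayley graph."""
    if n > 7:
        raise ValueError(f"BFS oracle limited to n <= 7, got {n}")
    start = tuple(range(1, n + 1))
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for p in frontier:
            d1 = dist[p] + 1
            for i in range(n):
                for j in range(i, n):
                    q = p[:i] + tuple(-x for x in reversed(p[i : j + 1])) + p[j + 1 :]
                    if q not in dist:
                        dist[q] = d1
                        nxt.append(q)
        frontier = nxt
    return dist


def bfs_distance_oracle(
    a: Sequence[SignedBlock], b: Sequence[SignedBlock], max_n: int = 7
) -> int:
    """Exact inversion distance by exhaustive BFS; verification use only."""
    if len(a) > max_n:
        raise ValueError(f"oracle refuses n={len(a)} > max_n={max_n}")
    perm = _to_signed_perm(a, b)
    return bfs_all_distances(len(perm))[perm]


def sorting_scenario(
    a: Sequence[SignedBlock], b: Sequence[SignedBlock]
) -> list[tuple[int, int]]:
    """One optimal inversion sequence (position pairs, inclusive) turning
    ``a`` into ``b``; its length equals :func:`inversion_distance`.

    Greedy: at each step some reversal lowers the distance by one
    (guaranteed by the theory since the distance is realised by a sorting
    sequence); pick the first such reversal in scan order.
    """
    current = tuple(a)
    d = inversion_distance(current, b)
    steps: list[tuple[int, int]] = []
    while d > 0:
        n = len(current)
        for i in range(n):
            found = False
            for j in range(i, n):
                cand = apply_inversion(current, i, j)
                if inversion_distance(cand, b) == d - 1:
                    steps.append((i, j))
                    current, d = cand, d - 1
                    found = True
                    break
            if found:
                break
        else:  # pragma: no cover - would contradict HP theory
            raise RuntimeError("no distance-reducing inversion found")
    return steps


# ---------------------------------------------------------------------------
# Ancestral insertion-configuration parsimony
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestralConfig:
    """A candidate ancestral arrangement: an insertion locus (the flanking
    base-block pair) plus the ordered, signed run of inserted blocks."""

    locus: tuple[str, str]
    inserted: Arrangement
    arrangement: Arrangement

    @property
    def name(self) -> str:
        ins = ",".join(str(b) for b in self.inserted)
        return f"{self.locus[0]}|{self.locus[1]}:{ins}"


DEFAULT_BASE = parse_arrangement("SB1+ SB2+ SB3+ SB4+")


def enumerate_ancestral_configs(
    base: Arrangement = DEFAULT_BASE,
    inserted: Sequence[str] = ("SB5", "SB6"),
    loci: Sequence[tuple[str, str]] | None = None,
) -> list[AncestralConfig]:
    """All candidate ancestral configurations: every inter-block gap of the
    base arrangement x every order x every sign assignment of the inserted
    run, deduplicated, in deterministic order.

    With the default 4-block base and two inserted blocks this yields
    3 loci x (2! orders x 2^2 signs) = 24 configurations.
    """
    base_ids = {b.id for b in base}
    if base_ids.intersection(inserted):
        raise ValueError("inserted blocks must be disjoint from the base layout")
    gaps = [(base[i].id, base[i + 1].id) for i in range(len(base) - 1)]
    if loci is not None:
        bad = [l for l in loci if tuple(l) not in gaps]
        if bad:
            raise ValueError(f"loci not inter-block gaps of the base: {bad}")
        gaps = [tuple(l) for l in loci]
    configs: list[AncestralConfig] = []
    seen: set[Arrangement] = set()
    for locus in gaps:
        gap_idx = next(i for i in range(len(base) - 1) if (base[i].id, base[i + 1].id) == locus)
        for order in itertools.permutations(inserted):
            for signs in itertools.product("+-", repeat=len(order)):
                run = tuple(SignedBlock(bid, s) for bid, s in zip(order, signs))
                arr = tuple(base[: gap_idx + 1]) + run + tuple(base[gap_idx + 1 :])
                if arr in seen:
                    continue
                seen.add(arr)
                configs.append(AncestralConfig(locus, run, arr))
    return configs


@dataclass
class ScenarioTable:
    """Scored candidate ancestral configurations.

    ``table`` has one row per configuration with per-species distances,
    total, rank and a minimal-set flag; ``minimal_configs`` lists every
    configuration attaining the minimum total (ties are all reported).
    """

    configs: list[AncestralConfig]
    table: pd.DataFrame

    @property
    def minimal_configs(self) -> list[AncestralConfig]:
        flags = self.table["is_minimal"].tolist()
        return [c for c, m in zip(self.configs, flags) if m]

    @property
    def min_total(self) -> int:
        return int(self.table["total"].min())


def score_scenarios(
    configs: Sequence[AncestralConfig],
    extant: Mapping[str, Arrangement],
    exclude_ids: Iterable[str] = frozenset({"SB5p"}),
) -> ScenarioTable:
    """Score each candidate ancestral configuration by the minimal inversion
    count to each extant arrangement (duplicated blocks excluded first)."""
    exclude = frozenset(exclude_ids)
    reduced = {sp: exclude_blocks(arr, exclude) for sp, arr in extant.items()}
    rows = []
    for cfg in configs:
        row: dict[str, object] = {
            "locus": f"{cfg.locus[0]}-{cfg.locus[1]}",
            "inserted": ",".join(str(b) for b in cfg.inserted),
        }
        total = 0
        for sp, arr in reduced.items():
            d = inversion_distance(cfg.arrangement, arr)
            row[f"d_{sp}"] = d
            total += d
        row["total"] = total
        rows.append(row)
    table = pd.DataFrame(rows)
    table["rank"] = table["total"].rank(method="min").astype(int)
    table["is_minimal"] = table["total"] == table["total"].min()
    return ScenarioTable(list(configs), table)


def load_xq_arrangements() -> dict[str, Arrangement]:
    """Shipped encoding of the extant signed block orders of the focal X
    locus in T. osimensis and T. tokunoshimensis (duplicated SB5' included
    under the ascii id ``SB5p``).  This is the package's reading of the
    published synteny maps; users may supply their own encoding."""
    import yaml

    text = resources.files("ytrace.data").joinpath("xq_region1_arrangements.yaml").read_text()
    raw = yaml.safe_load(text)
    return {sp: parse_arrangement(tokens) for sp, tokens in raw["arrangements"].items()}
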