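"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive each result from the definitions with plain
loops and no shared code with the package, so that agreement is evidence of
correctness rather than of shared bugs.
"""

from collections import Counter

_COMP = {"A": "T", "U": "A", "G": "C", "C": "G"}  # RNA base -> pairing DNA base
_WOBBLE = {("G", "T"), ("U", "G")}


def _wc(mb, tb):
    return _COMP.get(mb) == tb


def brute_force_sites(mirna, transcript, classes, allow_wobble=False, min_run=7):
    """Window-by-window seed-site enumeration; returns (class, start, end)."""
    m = mirna.upper().replace("T", "U")
    t = transcript.upper().replace("U", "T")
    n = len(t)
    rank = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3, "noncanonical": 4}
    cands = []
    for i in range(n):
        core6 = i + 6 <= n and all(_wc(m[1 + j], t[i + 5 - j]) for j in range(6))
        core7 = i + 7 <= n and all(_wc(m[1 + j], t[i + 6 - j]) for j in range(7))
        if "6mer" in classes and core6:
            cands.append(("6mer", i, i + 6))
        if "7mer-m8" in classes and core7:
            cands.append(("7mer-m8", i, i + 7))
        if "7mer-A1" in classes and core6 and i + 7 <= n and t[i + 6] == "A":
            cands.append(("7mer-A1", i, i + 7))
        if "8mer" in classes and core7 and i + 8 <= n and t[i + 7] == "A":
            cands.append(("8mer", i, i + 8))

    kept = []
    for cls, s, e in sorted(cands, key=lambda c: (rank[c[0]], c[1])):
        if any(ks <= s and e <= ke and rank[kc] < rank[cls] for kc, ks, ke in kept):
            continue
        kept.append((cls, s, e))

    if "noncanonical" in classes:
        seen = {(s, e) for _, s, e in kept}
        span = min(10, len(m))
        for anchor in range(n):
            paired = []
            for j in range(span):
                ti = anchor - j
                if ti < 0:
                    break
                ok = _wc(m[j], t[ti]) or (
                    allow_wobble and (j + 1) not in (2, 3, 4, 5, 6, 7) and (m[j], t[ti]) in _WOBBLE
                )
                paired.append(ok)
            # longest run of consecutive True
            best_len, best_start, cur = 0, None, None
            for j, ok in enumerate(paired + [False]):
                if ok and cur is None:
                    cur = j
                elif not ok and cur is not None:
                    if j - cur > best_len:
                        best_len, best_start = j - cur, cur
                    cur = None
            if best_len < min_run:
                continue
            s, e = anchor - (best_start + best_len - 1), anchor - best_start + 1
            if (s, e) in seen:
                continue
            if any(s < ke and ks < e for _, ks, ke in kept):
                continue
            seen.add((s, e))
            kept.append(("noncanonical", s, e))
    return sorted(kept, key=lambda c: (c[1], c[2], rank[c[0]]))


def brute_force_quantify(read_counts, refs, allow_3p_trim):
    """Exhaustive read-to-mature scan over all references and 3' variants."""
    assigned = Counter()
    unassigned = 0
    matures = {name: seq.upper().replace("U", "T") for name, seq in refs.items()}
    for read, count in read_counts.items():
        hits = []
        for name, mat in matures.items():
            if read == mat:
                hits.append((0, name))
            elif len(read) < len(mat) and len(mat) - len(read) <= allow_3p_trim:
                if mat[: len(read)] == read:
                    hits.append((len(mat) - len(read), name))
            elif len(read) > len(mat) and len(read) - len(mat) <= allow_3p_trim:
                if read[: len(mat)] == mat:
                    hits.append((len(read) - len(mat), name))
        if hits:
            assigned[min(hits)[1]] += count
        else:
            unassigned += count
    return assigned, unassigned


def brute_force_venn(sets):
    """Direct per-feature membership enumeration into the 7 regions."""
    names = list(sets)
    regions = {}
    universe = set().union(*sets.values())
    for f in universe:
        mask = tuple(f in sets[n] for n in names)
        regions.setdefault(mask, set()).add(f)
    return regions


def brute_force_degrees(edges):
    """Incidence counting over a unique-edge list."""
    deg = Counter()
    for u, v in set(map(frozenset, edges)):
        for node in (u, v):
            deg[node] += 1
    return dict(deg)


def brute_force_bfs(edges, seeds, radius):
    """Plain breadth-first search membership within `radius` hops."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    frontier = set(seeds)
    seen = set(seeds)
    for _ in range(radius):
        frontier = {w for n in frontier for w in adj.get(n, ())} - seen
        seen |= frontier
    return seen
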