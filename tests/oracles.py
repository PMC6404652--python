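"""Independent reference implementations used as test oracles.

Everything here is written as a direct, unoptimised transcription of the
definitions — affine-gap dynamic programming with explicit state matrices,
and discernibility matrices as literal quantifier enumeration — so it
shares no code path with the package.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_global_score(a, b, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0):
    """Optimal global alignment score; a gap of length L costs
    gap_open + (L-1) * gap_extend."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a-only column)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def smith_waterman_score(a, b, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0):
    """Optimal local alignment score (0 if no positive-scoring alignment)."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
            best = max(best, M[i][j])
    return best


def nw_identity(a, b, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0):
    """Identity (matches / alignment columns) of an optimal global
    alignment, via explicit traceback."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][i][j])
    matches = columns = 0
    while i > 0 or j > 0:
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            matches += a[i - 1] == b[j - 1]
            columns += 1
            prev = M[i][j] - s
            for st, T in (("M", M), ("X", X), ("Y", Y)):
                if T[i - 1][j - 1] == prev:
                    state = st
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            columns += 1
            val = X[i][j]
            if i > 1 and X[i - 1][j] + gap_extend == val:
                state = "X"
            elif M[i - 1][j] + gap_open == val:
                state = "M"
            else:
                state = "Y"
            i -= 1
        else:
            columns += 1
            val = Y[i][j]
            if j > 1 and Y[i][j - 1] + gap_extend == val:
                state = "Y"
            elif M[i][j - 1] + gap_open == val:
                state = "M"
            else:
                state = "X"
            j -= 1
    return matches / columns


# ---------------------------------------------------------------------------
# discernibility oracles: literal enumeration of the definitions


def oracle_candidates(db, group_id, supported):
    """Variants of the group consistent with every supported observed
    state; falls back to all variants when evidence excludes everything."""
    group = db.group(group_id)
    marker_by_key = {m.key: m for m in db.markers_of(group_id)}
    out = []
    for vid in sorted(group.variants):
        ok = True
        for key, states in supported.items():
            if marker_by_key[key].states[vid] not in states:
                ok = False
                break
        if ok:
            out.append(vid)
    return out if out else sorted(group.variants)


def oracle_gene_matrix(db, supported_by_group):
    """G(u, v) = 1 iff u, v are candidates of the same group and no marker
    with a supported observed state assigns them different states."""
    candidates = {
        g: oracle_candidates(db, g, sup) for g, sup in supported_by_group.items()
    }
    index = sorted(v for vs in candidates.values() for v in vs)
    G = {}
    group_of = {}
    for g, vs in candidates.items():
        for v in vs:
            group_of[v] = g
    for u in index:
        for v in index:
            if group_of[u] != group_of[v]:
                G[(u, v)] = False
                continue
            g = group_of[u]
            marker_by_key = {m.key: m for m in db.markers_of(g)}
            separated = False
            for key, states in supported_by_group[g].items():
                if not states:
                    continue
                m = marker_by_key[key]
                if m.states[u] != m.states[v]:
                    separated = True
            G[(u, v)] = not separated
    return index, G, candidates


def oracle_strain_matrix(db, candidates, G):
    """St(i, j) = 0 iff there is a detected group whose candidate set
    intersects i's repertoire such that j either lacks the group or carries
    only variants distinguishable from every such candidate of i."""
    rep = {
        strain: sorted(pairs) for strain, pairs in db.repertoires.items()
    }
    strains = sorted(
        s
        for s, pairs in rep.items()
        if any(g in candidates and v in candidates[g] for g, v in pairs)
    )

    def indist(v, u):
        if (v, u) not in G:
            return False  # u not a candidate: evidence excludes it
        return G[(v, u)]

    St = {}
    for i in strains:
        for j in strains:
            distinguishable = False
            for g in {g for g, _ in rep[i]}:
                if g not in candidates:
                    continue
                vi = [v for gg, v in rep[i] if gg == g and v in candidates[g]]
                if not vi:
                    continue
                uj = [u for gg, u in rep[j] if gg == g]
                if not uj:
                    distinguishable = True
                    break
                if all(not indist(v, u) for v in vi for u in uj):
                    distinguishable = True
                    break
            St[(i, j)] = not distinguishable
    return strains, St
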