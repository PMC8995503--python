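"""Independent brute-force / reference oracles used by the test suite.

Everything here is deliberately naive and separate from the package
implementation paths it checks.
"""

from __future__ import annotations

import itertools
import subprocess

WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def revcomp(s: str) -> str:
    return "".join(WC[b] for b in reversed(s))


def brute_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum non-crossing WC pairing by exhaustive recursion."""
    seq = seq.upper().replace("U", "T")

    def rec(avail: tuple[int, ...]) -> int:
        if len(avail) < 2:
            return 0
        i = avail[0]
        best = rec(avail[1:])
        for idx in range(1, len(avail)):
            j = avail[idx]
            if j - i <= min_loop:
                continue
            if WC[seq[i]] == seq[j]:
                inside = avail[1:idx]
                outside = avail[idx + 1 :]
                best = max(best, 1 + rec(inside) + rec(outside))
        return best

    return rec(tuple(range(len(seq))))


def brute_self_complementary(s: str, window: int) -> bool:
    """All substring pairs, any lengths >= window, gap >= 3, either order."""
    n = len(s)
    for w in range(window, n + 1):
        for i in range(n - w + 1):
            for j in range(n - w + 1):
                if revcomp(s[i : i + w]) != s[j : j + w]:
                    continue
                lo, hi = sorted((i, j))
                if hi - (lo + w) >= 3:
                    return True
    return False


def brute_enumerate_stems(length: int, at_count: int, motifs, window):
    """Enumerate every ACGT string and filter, independent of design.py."""
    out = []
    for combo in itertools.product("ACGT", repeat=length):
        s = "".join(combo)
        if sum(1 for b in s if b in "AT") != at_count:
            continue
        if motifs and any(m in s or m in revcomp(s) for m in motifs):
            continue
        if window is not None and brute_self_complementary(s, window):
            continue
        out.append(s)
    return out


def rnaeval_hairpins(structures) -> list[float]:
    """Fixed-structure free energies from the reference implementation.

    Each structure must be a perfect stem-loop; dot-bracket strings are
    derived from the intended pairing.
    """
    blocks = []
    for hp in structures:
        k = len(hp.pairing.pairs)
        loop = hp.total_length - 2 * k
        db = "(" * k + "." * loop + ")" * k
        blocks.append(hp.insert_sequence.replace("T", "U") + "\n" + db)
    proc = subprocess.run(
        ["RNAeval"], input="\n".join(blocks), capture_output=True, text=True,
        check=True,
    )
    vals = []
    for line in proc.stdout.splitlines():
        line = line.strip()
        if line.endswith(")") and " (" in line:
            vals.append(float(line.rsplit("(", 1)[1].rstrip(")")))
    return vals


def brute_panel_cost(pool, k: int, lo: float, hi: float) -> float:
    """Best total grid deviation over all k-subsets of the in-range pool."""
    grid = [lo + (hi - lo) * t / (k - 1) for t in range(k)]
    inr = sorted(p for p in pool if lo <= p <= hi)
    best = None
    for combo in itertools.combinations(inr, k):
        cost = sum(abs(c - g) for c, g in zip(combo, grid))
        if best is None or cost < best:
            best = cost
    return best


def naive_masked_mean_ratio(green, red, mask):
    """Double-loop mean of green/red over masked pixels."""
    total = 0.0
    n = 0
    h = len(mask)
    w = len(mask[0])
    for r in range(h):
        for c in range(w):
            if mask[r][c]:
                total += green[r][c] / red[r][c]
                n += 1
    return (total / n) if n else None, n


def naive_site_scan(seq: str, site: str):
    """All occurrences of site on both strands, palindromes once."""
    seq, site = seq.upper(), site.upper()
    rc = revcomp(site)
    hits = []
    for i in range(len(seq) - len(site) + 1):
        if seq[i : i + len(site)] == site:
            hits.append((i, 1))
        elif rc != site and seq[i : i + len(site)] == rc:
            hits.append((i, -1))
    return hits
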