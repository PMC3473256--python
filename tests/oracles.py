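"""Independent brute-force oracles for the comparison engine tests.

These deliberately avoid the production code paths: superlocus grouping is
recomputed as the transitive closure of the pairwise proximity relation with
a quadratic scan + union-find, and superlocus verdicts are recomputed by
exhaustively enumerating haplotype pairings, per-record phase swaps (in both
samples) and bounded-length completions of no-called stretches.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np

from twindiff.core import ReferenceGenome, VariantCall

FILL_MAX = 6
_ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# superlocus partition oracle (quadratic scan + union-find)


def partition_oracle(spans: list[tuple[int, int]], merge_gap: int) -> list[set[int]]:
    """Groups of span indices under the transitive closure of
    'reference spans within merge_gap of each other'."""
    n = len(spans)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            (b1, e1), (b2, e2) = spans[i], spans[j]
            gap = max(b1, b2) - min(e1, e2)
            if gap <= merge_gap:
                union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=min)


# ---------------------------------------------------------------------------
# verdict oracle


def _hap_tokens(ref, contig, begin, end, calls, hap):
    """Haplotype as a list of ('lit', str) / ('wild', None) tokens."""
    out = []
    cursor = begin
    for c in sorted(calls, key=lambda c: (c.begin, c.end)):
        out.append(("lit", ref.fetch(contig, cursor, c.begin)))
        allele = c.allele1 if hap == 0 else c.allele2
        if c.vartype == "no-call" or allele is None:
            out.append(("wild", None))
        else:
            out.append(("lit", allele))
        cursor = c.end
    out.append(("lit", ref.fetch(contig, cursor, end)))
    return out


def _completions(tokens, max_fill=FILL_MAX):
    """Every concrete string obtainable by filling each wildcard with a DNA
    string of length 0..max_fill."""
    wild_positions = [i for i, (kind, _) in enumerate(tokens) if kind == "wild"]
    fills = []
    for length in range(max_fill + 1):
        fills.extend("".join(t) for t in itertools.product(_ALPHABET, repeat=length))
    results = set()
    for combo in itertools.product(fills, repeat=len(wild_positions)):
        parts = []
        w = 0
        for kind, value in tokens:
            if kind == "lit":
                parts.append(value)
            else:
                parts.append(combo[w])
                w += 1
        results.add("".join(parts))
    return results


def _concrete(tokens):
    if any(kind == "wild" for kind, _ in tokens):
        return None
    return "".join(v for _, v in tokens)


def _swapped_variants(calls):
    """All per-record phase reassignments of the het records."""
    hets = [
        i
        for i, c in enumerate(calls)
        if c.vartype not in ("ref", "no-call") and c.allele1 != c.allele2
    ]
    for mask in range(1 << len(hets)):
        trial = list(calls)
        for bit, idx in enumerate(hets):
            if mask >> bit & 1:
                c = trial[idx]
                trial[idx] = replace(c, allele1=c.allele2, allele2=c.allele1)
        yield trial


def _pairing_equal(a1, a2, b1, b2):
    return (a1 == b1 and a2 == b2) or (a1 == b2 and a2 == b1)


def classify_oracle(sl, ref: ReferenceGenome, max_fill: int = FILL_MAX) -> str:
    """Exhaustive-enumeration verdict for one superlocus."""
    contig, begin, end = sl.contig, sl.begin, sl.end

    def haps(calls):
        return [_hap_tokens(ref, contig, begin, end, calls, h) for h in (0, 1)]

    toks_a, toks_b = haps(sl.calls_a), haps(sl.calls_b)
    conc_a = [_concrete(t) for t in toks_a]
    conc_b = [_concrete(t) for t in toks_b]
    full_a = all(s is not None for s in conc_a)
    full_b = all(s is not None for s in conc_b)
    var_a = any(c.is_variant(ref) for c in sl.calls_a)
    var_b = any(c.is_variant(ref) for c in sl.calls_b)

    if full_a and full_b:
        if _pairing_equal(conc_a[0], conc_a[1], conc_b[0], conc_b[1]):
            return "identical"
        if not var_b:
            return "onlyA"
        if not var_a:
            return "onlyB"
        for trial_a in _swapped_variants(sl.calls_a):
            sa = [_concrete(t) for t in haps(trial_a)]
            for trial_b in _swapped_variants(sl.calls_b):
                sb = [_concrete(t) for t in haps(trial_b)]
                if _pairing_equal(sa[0], sa[1], sb[0], sb[1]):
                    return "phase-mismatch"
        return "mismatch"

    if full_b and not var_b and var_a:
        return "onlyA"
    if full_a and not var_a and var_b:
        return "onlyB"
    comp_a = [_completions(t, max_fill) for t in toks_a]
    comp_b = [_completions(t, max_fill) for t in toks_b]
    for xb in ((0, 1), (1, 0)):
        if comp_a[0] & comp_b[xb[0]] and comp_a[1] & comp_b[xb[1]]:
            return "consistent"
    return "mismatch"


# ---------------------------------------------------------------------------
# random instance generator


def random_callset_pair(rng: np.random.Generator, ref: ReferenceGenome):
    """Two small random call sets on one contig, engineered so that bounded
    completion (FILL_MAX) is provably sufficient for the oracle: alleles and
    spans are at most 2 bp and only one sample per instance carries
    no-called haplotype stretches (at most one)."""
    contig = next(iter(ref.contigs))
    length = ref.length(contig)

    def random_calls():
        n = int(rng.integers(0, 4))
        calls = []
        cursor = 2
        for _ in range(n):
            pos = cursor + int(rng.integers(0, 8))
            if pos > length - 6:
                break
            u = rng.random()
            qual = float(rng.uniform(20, 80))
            if u < 0.5:
                b = ref.fetch(contig, pos, pos + 1)
                alts = [x for x in "ACGT" if x != b]
                alt = alts[int(rng.integers(0, 3))]
                z = rng.random()
                if z < 0.5:
                    a1, a2 = b, alt
                elif z < 0.8:
                    a1, a2 = alt, alt
                else:
                    other = alts[int(rng.integers(0, 3))]
                    a1, a2 = alt, other
                call = VariantCall(contig, pos, pos + 1, "snp", a1, a2, qual)
                cursor = pos + 1 + 4
            elif u < 0.75:
                seq = "".join(
                    "ACGT"[int(rng.integers(0, 4))]
                    for _ in range(int(rng.integers(1, 3)))
                )
                a1, a2 = (seq, "") if rng.random() < 0.6 else (seq, seq)
                call = VariantCall(contig, pos, pos, "ins", a1, a2, qual)
                cursor = pos + 4
            else:
                span = int(rng.integers(1, 3))
                ref_seq = ref.fetch(contig, pos, pos + span)
                a1, a2 = ("", ref_seq) if rng.random() < 0.6 else ("", "")
                call = VariantCall(contig, pos, pos + span, "del", a1, a2, qual)
                cursor = pos + span + 4
            if rng.random() < 0.5 and call.allele1 != call.allele2:
                call = replace(call, allele1=call.allele2, allele2=call.allele1)
            calls.append(call)
        return calls

    calls_a = random_calls()
    if rng.random() < 0.5 and calls_a:
        # correlated pair: B inherits A's records, possibly rephased/dropped
        calls_b = []
        for c in calls_a:
            if rng.random() < 0.15:
                continue
            if rng.random() < 0.4 and c.allele1 != c.allele2:
                c = replace(c, allele1=c.allele2, allele2=c.allele1)
            calls_b.append(c)
    else:
        calls_b = random_calls()

    # wildcards in at most one sample per instance
    if rng.random() < 0.4:
        which = calls_a if rng.random() < 0.5 else calls_b
        if which and rng.random() < 0.5:
            idx = int(rng.integers(0, len(which)))
            c = which[idx]
            if c.is_fully_called():
                which[idx] = (
                    replace(c, allele1=None)
                    if rng.random() < 0.5
                    else replace(c, allele2=None)
                )
        else:
            taken = sorted((c.begin, max(c.end, c.begin + 1)) for c in which)
            for _ in range(20):
                pos = int(rng.integers(2, length - 4))
                span = int(rng.integers(1, 3))
                if all(pos + span + 1 <= b or pos >= e + 1 for b, e in taken):
                    which.append(
                        VariantCall(contig, pos, pos + span, "no-call", None, None)
                    )
                    break
    return calls_a, calls_b
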