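"""Independent brute-force oracles, kept deliberately literal and separate from
the implementation: every offset is tested directly against the
two-consecutive-mismatch condition, character by character."""


def _mismatch(a: str, b: str) -> bool:
    return a != b or a == "N" or b == "N"


def brute_forward_breakpoint(obs: str, ref: str):
    """Literal left-to-right scan: first offset i where positions i and i+1
    both mismatch under left alignment."""
    n = min(len(obs), len(ref))
    for i in range(n - 1):
        if _mismatch(obs[i], ref[i]) and _mismatch(obs[i + 1], ref[i + 1]):
            return i
    return None


def brute_reverse_breakpoint(obs: str, ref: str):
    """Literal right-to-left scan under right alignment; returns the reference
    position just after the last disrupted base (half-open end)."""
    n = min(len(obs), len(ref))
    for j in range(n - 1):
        if _mismatch(obs[len(obs) - 1 - j], ref[len(ref) - 1 - j]) and _mismatch(
            obs[len(obs) - 2 - j], ref[len(ref) - 2 - j]
        ):
            return len(ref) - j
    return None


def brute_rank_patterns(keys: list[tuple]) -> list[tuple]:
    """Naive count-and-sort pattern ranking oracle.

    keys are (deletion_start, deletion_end, insertion) tuples; returns keys
    sorted by descending count, then smaller deletion start, then insertion.
    """
    counts: dict[tuple, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    none_low = lambda s: -1 if s is None else s
    return sorted(counts, key=lambda k: (-counts[k], none_low(k[0]), k[2]))
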