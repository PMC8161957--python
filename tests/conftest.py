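import numpy as np
import pytest

from grnmap.simulate import FixtureSpec, generate_fixture


def naive_scan(seq: str, pwm, threshold: float):
    """Independent brute-force motif scanner: enumerate every window on both
    strands and score it with plain Python sums. Returns (start, strand, score,
    rel_score) tuples in sequence-local coordinates."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = pwm.width
    lo = pwm.logodds
    span = pwm.max_score - pwm.min_score
    hits = []
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w]
        for strand in ("+", "-"):
            s = window if strand == "+" else "".join(comp.get(b, "N") for b in reversed(window))
            score = 0.0
            ok = True
            for j, b in enumerate(s):
                if b not in base_idx:
                    ok = False
                    break
                score += float(lo[base_idx[b], j])
            if not ok or score != score or score == float("-inf"):
                continue
            rel = 1.0 if span == 0 else (score - pwm.min_score) / span
            if rel >= threshold:
                hits.append((start, strand, score, rel))
    return hits


def random_pfm(rng, width=None, sharp=False):
    from grnmap.motifs import MotifPfm

    w = width or int(rng.integers(5, 13))
    if sharp:
        counts = np.full((4, w), 5.0)
        for j in range(w):
            counts[rng.integers(4), j] = 85.0
    else:
        counts = rng.uniform(0.5, 30.0, size=(4, w))
    return MotifPfm(tf_name=f"TF_R{w}", counts=counts)


def random_sequence(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def default_fixture():
    """The generator's study conditions: 20 TFs, 50 genes, 30 planted edges,
    500 cells per type. Built once per session."""
    return generate_fixture(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def small_fixture():
    return generate_fixture(FixtureSpec(seed=3, n_cells_per_type=60, n_genes=12,
                                        n_tfs=6, n_enhancers=10, n_planted_edges=8,
                                        n_snps_disrupting=3, n_snps_neutral=3))
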