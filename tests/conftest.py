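import numpy as np
import pytest

from peba.scoring import ScoreMatrix

ALPHA = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture
def rng():
    return np.random.default_rng(20240228)


def random_gapped_rows(rng, k, n_cols, gap_frac=0.25):
    """k random gapped rows of n_cols columns; no row is all gaps."""
    rows = []
    for idx in range(k):
        while True:
            chars = [
                "-" if rng.random() < gap_frac else str(rng.choice(ALPHA))
                for _ in range(n_cols)
            ]
            if any(c != "-" for c in chars):
                break
        rows.append((f"s{idx}", "".join(chars)))
    return rows


def random_score_matrix(rng, max_side=5, low=-12.0, high=12.0):
    m, n = rng.integers(1, max_side + 1, 2)
    return ScoreMatrix(values=rng.uniform(low, high, (int(m), int(n))),
                       origin="substitution")


def write_msf(path, rows):
    """Write rows as a GCG MSF file in 50-column interleaved blocks."""
    n_cols = len(rows[0][1])
    lines = ["PileUp", "", f" MSF: {n_cols}  Type: P  Check: 0 ..", ""]
    for sid, row in rows:
        lines.append(f" Name: {sid}  Len: {n_cols}  Check: 0  Weight: 1.0")
    lines += ["", "//", ""]
    for start in range(0, n_cols, 50):
        for sid, row in rows:
            lines.append(f"{sid}  {row[start:start + 50]}")
        lines.append("")
    path.write_text("\n".join(lines) + "\n")
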