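import numpy as np
import pytest

from sipfft.features import extract_features
from sipfft.synthetic import SyntheticSpec, generate_dataset

# A small PSI-BLAST ASCII PSSM in the real layout: position, residue,
# 20 log-odds, 20 weighted percentages, information content, weight.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def make_pssm_text(matrix: np.ndarray, sequence: str, order: str = PSIBLAST_ORDER) -> str:
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts",
        "            " + "  ".join(order) + "   " + "  ".join(order),
    ]
    for i, row in enumerate(matrix):
        scores = " ".join(f"{int(v):3d}" for v in row)
        pcts = " ".join("0" for _ in range(20))
        lines.append(f"{i + 1:5d} {sequence[i]}  {scores}  {pcts}  0.30 0.10")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1337     0.3110"]
    return "\n".join(lines)


@pytest.fixture
def pssm_file(tmp_path):
    rng = np.random.default_rng(7)
    matrix = rng.integers(-8, 9, size=(7, 20))
    seq = "MKVLIAG"
    path = tmp_path / "P00007.pssm"
    path.write_text(make_pssm_text(matrix, seq))
    return path, matrix, seq


@pytest.fixture(scope="session")
def high_signal_features():
    """Balanced 100+100 synthetic dataset at signal-to-noise 5, FFT features."""
    profiles, labels = generate_dataset(SyntheticSpec(n_pos=100, n_neg=100, seed=11))
    return extract_features(profiles, labels=labels, extractor="FFT")
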