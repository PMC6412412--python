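"""Synthetic PSSM datasets with class-dependent spectral structure.

The generator emulates length-filtered protein profile sets: each
protein is an N x 20 matrix with N drawn uniformly from a length range.
Negatives are pure Gaussian noise. Positives superimpose a sinusoidal
position signal, amplitude · sin(2π·α / period), on a fixed subset of
columns — a class-level periodic signature that survives the Gram-matrix
contraction and concentrates in a few Fourier coefficients, so the FFT
descriptor has a detectable target while covariance and DCT descriptors
retain partial power. The signal-column subset is drawn once per
dataset and shared by all positives; a per-protein subset would make
positives mutually dissimilar and defeat any distance-based learner.

No attempt is made to mimic real PSSM marginal distributions or BLAST
score calibration; see docs/methods.md for what this does and does not
validate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sipfft.pssm_io import CANONICAL_ORDER, PssmProfile, write_psiblast_pssm


@dataclass
class SyntheticSpec:
    """Parameters of the class-structured PSSM simulation.

    Defaults give a balanced 100 + 100 protein set with signal-to-noise
    5, the regime where the pipeline should separate the classes almost
    perfectly; ``imbalanced()`` mirrors a 1441:15938 positive:negative
    census scaled down tenfold.
    """

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (50, 300)
    signal_period: int = 8
    signal_amplitude: float = 5.0
    noise_sd: float = 1.0
    n_signal_cols: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be >= 1")
        if self.length_range[0] < 2 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length range")
        if self.signal_amplitude < 0:
            raise ValueError("signal amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")
        if not 1 <= self.n_signal_cols <= 20:
            raise ValueError("n_signal_cols must be in 1..20")

    @classmethod
    def imbalanced(cls, **kwargs) -> "SyntheticSpec":
        """Human-census class ratio (1441:15938) scaled down tenfold."""
        kwargs.setdefault("n_pos", 144)
        kwargs.setdefault("n_neg", 1594)
        return cls(**kwargs)


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(CANONICAL_ORDER), size=n))


def generate_dataset(spec: SyntheticSpec) -> tuple[list[PssmProfile], np.ndarray]:
    """Simulate labelled profiles; returns (profiles, 0/1 labels).

    Fully deterministic given ``spec.seed``. Label 1 marks the
    signal-bearing (self-interacting analogue) class.
    """
    rng = np.random.default_rng(spec.seed)
    signal_cols = rng.choice(20, size=spec.n_signal_cols, replace=False)
    profiles: list[PssmProfile] = []
    labels = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    for i, label in enumerate(labels):
        n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        matrix = rng.normal(0.0, spec.noise_sd, size=(n, 20))
        if label == 1 and spec.signal_amplitude > 0:
            alpha = np.arange(1, n + 1)
            wave = spec.signal_amplitude * np.sin(2 * np.pi * alpha / spec.signal_period)
            matrix[:, signal_cols] += wave[:, None]
        profiles.append(
            PssmProfile(
                protein_id=f"SYN{i + 1:05d}",
                matrix=matrix,
                sequence=_random_sequence(n, rng),
                residue_order=CANONICAL_ORDER,
                source="psiblast_ascii",
            )
        )
    return profiles, labels


def write_fixture(
    profiles: list[PssmProfile],
    out_dir: str | Path,
    labels: np.ndarray | None = None,
) -> list[Path]:
    """Write profiles as PSI-BLAST ASCII files (plus labels.tsv if given)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in profiles:
        path = out_dir / f"{p.protein_id}.pssm"
        write_psiblast_pssm(p, path)
        paths.append(path)
    if labels is not None:
        lines = ["id\tlabel"] + [
            f"{p.protein_id}\t{int(l)}" for p, l in zip(profiles, labels)
        ]
        (out_dir / "labels.tsv").write_text("\n".join(lines) + "\n")
    return paths
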