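"""Shared fixtures: synthetic truth sets and hand-built SAM helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from modpolisher.synth import SynthParams, SyntheticTruthSet, generate


@pytest.fixture(scope="session")
def default_truth_set(tmp_path_factory) -> SyntheticTruthSet:
    """One default-condition truth set (50 kb, 40 modified, 20 decoys)."""
    out = tmp_path_factory.mktemp("fixture_seed0")
    return generate(SynthParams(), seed=0, out_dir=out)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(1234))


def random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def mutate(seq: str, rng: np.random.Generator, n: int) -> str:
    """Apply exactly n substitutions at distinct positions."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def write_sam(path: Path, contig: str, length: int,
              records: list[tuple]) -> Path:
    """Write a minimal SAM: records are (name, flag, pos0, cigar, seq, qual).

    ``qual`` is either a string of Phred+33 characters or '*'.
    """
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:{contig}\tLN:{length}"]
    for name, flag, pos0, cigar, seq, qual in records:
        lines.append(f"{name}\t{flag}\t{contig}\t{pos0 + 1}\t60\t{cigar}\t"
                     f"*\t0\t0\t{seq}\t{qual}")
    path.write_text("\n".join(lines) + "\n")
    return path


def phred(*scores: int) -> str:
    return "".join(chr(s + 33) for s in scores)
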