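"""Shared fixtures: small planted cohorts and an in-memory FCS writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from cytodeep import default_benchmark_spec, generate


@pytest.fixture(scope="session")
def small_cohort():
    """3 canonical + 1 novel population, 2,000 cells, 6 markers, seeded."""
    specs = default_benchmark_spec(3, 1, 6, separation=6.0, seed=5)
    table, observed, truth = generate(specs, 2000, labeled_fraction=0.6, seed=5)
    return specs, table, observed, truth


@pytest.fixture(scope="session")
def separable_2pop():
    """Two far-separated 1-marker-rich populations for classifier checks."""
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(0.0, 1.0, (200, 1)), rng.normal(10.0, 1.0, (200, 1))])
    y = np.array(["a"] * 200 + ["b"] * 200, dtype=object)
    return X, y


def write_minimal_fcs(path, values: np.ndarray, names: list[str]) -> None:
    """Write a tiny FCS 3.0 file (float32, little-endian) for round-trips."""
    values = np.asarray(values, dtype=np.float32)
    n_tot, n_par = values.shape
    kw = {
        "$DATATYPE": "F", "$BYTEORD": "1,2,3,4", "$MODE": "L",
        "$PAR": str(n_par), "$TOT": str(n_tot),
    }
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = f"ch{i}"
        kw[f"$P{i}S"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}R"] = "262144"
        kw[f"$P{i}E"] = "0,0"
    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    text_bytes = text.encode("ascii")
    header_len = 58
    text_begin = header_len
    text_end = text_begin + len(text_bytes) - 1
    data_begin = text_end + 1
    data_end = data_begin + values.size * 4 - 1
    header = (
        b"FCS3.0    "
        + f"{text_begin:8d}{text_end:8d}{data_begin:8d}{data_end:8d}".encode()
        + f"{0:8d}{0:8d}".encode()
    )
    data = struct.pack(f"<{values.size}f", *values.ravel())
    with open(path, "wb") as fh:
        fh.write(header + text_bytes + data)
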