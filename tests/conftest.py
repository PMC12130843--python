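"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from eccperm.sfstate import SiteGeometry

ASP_POT_ITP = """\
; illustrative ASP + K+ topology fragment
[ moleculetype ]
; name  nrexcl
ASPX    3

[ atoms ]
;   nr       type  resnr residue  atom   cgnr     charge       mass
     1          N      1    ASP      N      1      -0.47     14.007 ; backbone
     2         HN      1    ASP     HN      1       0.31      1.008
     3        CT1      1    ASP     CA      1       0.07     12.011
     4        HB1      1    ASP     HA      1       0.09      1.008
     5       CT2A      1    ASP     CB      2      -0.28     12.011
     6        HA2      1    ASP    HB1      2       0.09      1.008
     7        HA2      1    ASP    HB2      2       0.09      1.008
     8         CC      1    ASP     CG      2       0.62     12.011
     9         OC      1    ASP    OD1      2      -0.76     15.999
    10         OC      1    ASP    OD2      2      -0.76     15.999
    11          C      1    ASP      C      3       0.51     12.011
    12          O      1    ASP      O      3      -0.51     15.999
    13        POT      2    POT    POT      4       1.00     39.098
"""

ASP_GROUP = {"ASP": ["CB", "HB1", "HB2", "CG", "OD1", "OD2"], "POT": ["POT"]}


@pytest.fixture
def asp_itp(tmp_path):
    p = tmp_path / "asp.itp"
    p.write_text(ASP_POT_ITP)
    return p


@pytest.fixture
def geometry() -> SiteGeometry:
    """Canonical SF geometry: planes 0.3 nm apart, 0.4 nm caps, 0.25 nm radius."""
    return SiteGeometry(
        plane_z=(1.0, 1.3, 1.6, 1.9, 2.2),
        s0_cap=0.4,
        scav_depth=0.4,
        axis_radius=0.25,
        axis_xy=(2.0, 2.0),
    )


def mfpt_oracle(stride: float, codes: list[str]) -> dict[tuple[str, str], float]:
    """Brute-force O(n^2) MFPT scan, independent of the package implementation.

    MFPT(A->B) = mean over entries into A of the time to the first subsequent
    frame in B; passages not completed before the end are censored.
    """
    n = len(codes)
    states = sorted(set(codes))
    out: dict[tuple[str, str], float] = {}
    for a in states:
        entries = [
            i for i in range(n) if codes[i] == a and (i == 0 or codes[i - 1] != a)
        ]
        for b in states:
            if b == a:
                continue
            times = []
            for e in entries:
                for j in range(e, n):
                    if codes[j] == b:
                        times.append((j - e) * stride)
                        break
            if times:
                out[(a, b)] = sum(times) / len(times)
    return out


def transition_count_oracle(codes: list[str]) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for a, b in zip(codes[:-1], codes[1:]):
        if a != b:
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def rdf_histogram_oracle(ref_frames, tgt_frames, box, edges) -> np.ndarray:
    """Brute-force pair-distance histogram with explicit per-pair minimum image."""
    box = np.asarray(box, dtype=float)
    counts = np.zeros(len(edges) - 1)
    for ref, tgt in zip(ref_frames, tgt_frames):
        for p in ref:
            for t in tgt:
                d = t - p
                for k in range(3):
                    d[k] -= box[k] * round(d[k] / box[k])
                r = float(np.sqrt((d * d).sum()))
                if r <= 1e-12:
                    continue
                for b in range(len(edges) - 1):
                    if edges[b] <= r < edges[b + 1]:
                        counts[b] += 1
                        break
    return counts
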