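"""DNA fingerprints over a core marker panel and 2D-barcode payloads.

A fingerprint is, per sample, the ordered genotype-call string over the
panel loci plus a rendering class per call used for the standard color
scheme: homozygotes colored by base (C/C yellow, A/A green, T/T blue,
G/G purple), every heterozygote white, missing calls gray.  The barcode
payload keeps the full two-allele call that the color rendering loses.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

RENDER_COLORS = {
    "CC": "yellow",
    "AA": "green",
    "TT": "blue",
    "GG": "purple",
    "HET": "white",
    "MISSING": "gray",
}

_PAYLOAD_MAGIC = "FP1"


@dataclass
class Fingerprint:
    samples: list[str]
    panel: list[str]  # locus ids in panel order
    calls: list[list[str]]  # per sample, per panel locus: "AG", "CC", ... or "--"
    classes: list[list[str]]  # rendering class per call
    panel_hash: str

    def call_string(self, sample: str) -> str:
        return "|".join(self.calls[self.samples.index(sample)])

    def matrix(self) -> pd.DataFrame:
        """Rows = panel loci, columns = samples (fingerprint-map orientation)."""
        data = np.array(self.calls).T
        return pd.DataFrame(data, index=self.panel, columns=self.samples)


def _panel_hash(panel: Sequence[str]) -> str:
    return hashlib.sha1("|".join(panel).encode()).hexdigest()[:8]


def _render_class(call: tuple[str, str] | None) -> str:
    if call is None:
        return "MISSING"
    a, b = call
    return a * 2 if a == b else "HET"


def build_fingerprint(g: GenotypeMatrix, panel: Sequence[str]) -> Fingerprint:
    """Per-sample call strings over ``panel`` (locus ids, kept in order)."""
    idx = [g.locus_index(lid) for lid in panel]  # raises on absent locus
    calls: list[list[str]] = []
    classes: list[list[str]] = []
    for i in range(g.n_samples):
        row_calls, row_classes = [], []
        for j in idx:
            call = g.call(i, j)
            row_calls.append("--" if call is None else "".join(call))
            row_classes.append(_render_class(call))
        calls.append(row_calls)
        classes.append(row_classes)
    return Fingerprint(
        samples=list(g.samples),
        panel=list(panel),
        calls=calls,
        classes=classes,
        panel_hash=_panel_hash(panel),
    )


@dataclass
class DistinguishabilityReport:
    mismatches: pd.DataFrame  # symmetric int matrix, zero diagonal
    compared: pd.DataFrame  # loci non-missing in both
    indistinguishable: list[tuple[str, str]]  # zero mismatches over >=1 shared locus
    uncomparable: list[tuple[str, str]]  # zero shared non-missing loci


def pairwise_distinguishability(fp: Fingerprint) -> DistinguishabilityReport:
    """Mismatch counts over loci called in both samples of each pair.

    A pair with zero mismatches over at least one shared locus is
    indistinguishable; a pair with no shared called loci is flagged
    uncomparable, never reported as identical.
    """
    if len(fp.samples) < 2:
        raise ValueError("need at least 2 samples")
    arr = np.array(fp.calls)  # (n, p) strings
    called = arr != "--"
    n = len(fp.samples)
    mism = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = called[i] & called
        comp[i] = both.sum(axis=1)
        mism[i] = ((arr[i] != arr) & both).sum(axis=1)
    indist, uncomp = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if comp[i, j] == 0:
                uncomp.append((fp.samples[i], fp.samples[j]))
            elif mism[i, j] == 0:
                indist.append((fp.samples[i], fp.samples[j]))
    labels = fp.samples
    return DistinguishabilityReport(
        mismatches=pd.DataFrame(mism, index=labels, columns=labels),
        compared=pd.DataFrame(comp, index=labels, columns=labels),
        indistinguishable=indist,
        uncomparable=uncomp,
    )


def barcode_payload(fp: Fingerprint, sample: str) -> str:
    """Deterministic text payload for one sample's 2D barcode.

    Grammar: ``FP1|sample=<label>|panel=<hash>|<id>=<call>;...`` with
    locus=call pairs in panel order.  Round-trips through
    :func:`parse_barcode_payload`.
    """
    if sample not in fp.samples:
        raise KeyError(f"unknown sample {sample!r}")
    row = fp.calls[fp.samples.index(sample)]
    pairs = ";".join(f"{lid}={call}" for lid, call in zip(fp.panel, row))
    return f"{_PAYLOAD_MAGIC}|sample={sample}|panel={fp.panel_hash}|{pairs}"


def parse_barcode_payload(payload: str) -> dict:
    """Parse a payload back to sample label, panel hash and ordered calls."""
    magic, sample_f, panel_f, pairs_f = payload.split("|", 3)
    if magic != _PAYLOAD_MAGIC:
        raise ValueError(f"unrecognized payload magic {magic!r}")
    sample = sample_f.removeprefix("sample=")
    panel_hash = panel_f.removeprefix("panel=")
    loci, calls = [], []
    for item in pairs_f.split(";"):
        lid, call = item.rsplit("=", 1)
        loci.append(lid)
        calls.append(call)
    return {"sample": sample, "panel_hash": panel_hash, "loci": loci, "calls": calls}
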