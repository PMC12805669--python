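"""Tab-separated trace logs (header line, then numeric rows) readable by
the usual MCMC trace viewers."""

from __future__ import annotations

import numpy as np


class TraceFormatError(ValueError):
    pass


def write_trace(path, header, rows) -> None:
    rows = [list(map(float, r)) for r in rows]
    for r in rows:
        if len(r) != len(header):
            raise TraceFormatError("row length does not match header")
        if not np.all(np.isfinite(r)):
            raise TraceFormatError("non-finite value in trace row")
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(f"{v:.10g}" for v in r) + "\n")


def read_trace(path):
    """Returns (header, rows ndarray)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TraceFormatError("empty trace file")
    header = lines[0].lstrip("#").split("\t")
    rows = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise TraceFormatError(f"row has {len(fields)} fields, expected {len(header)}")
        rows.append([float(x) for x in fields])
    arr = np.array(rows)
    if arr.size and not np.all(np.isfinite(arr)):
        raise TraceFormatError("non-finite value in trace")
    return header, arr
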