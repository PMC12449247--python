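"""Read, validate and write Tapestri-style ``.h5`` files.

Fixed on-disk schema (all strings UTF-8):

.. code-block:: text

    /assays/dna_read_counts/layers/read_counts   cells x A   int
    /assays/dna_read_counts/ca/{id,chrom,start,end}          length A
    /assays/dna_variants/layers/{AF,DP,GQ,NGT}   cells x V
    /assays/dna_variants/ca/{chrom,pos,ref,alt}              length V
    /assays/dna_variants/ra/barcode                          length cells
    /metadata/<key>                              scalar strings

The reader additionally maps a small set of path aliases used by genuine
Tapestri exports (e.g. ``CHROM``/``POS`` column names) onto this schema, so
real pipeline files load where the layer names match.
"""

from __future__ import annotations

import os
from typing import Union

import h5py
import numpy as np

from .dataset import (
    Amplicon,
    ConsistencyError,
    REQUIRED_METADATA_KEYS,
    SchemaError,
    ScdnaDataset,
    ValidationReport,
    Variant,
)

PathLike = Union[str, os.PathLike]

_VARIANT_LAYERS = ("AF", "DP", "GQ", "NGT")

# alias -> canonical name, checked in order, for variant column annotations
_CA_ALIASES = {
    "chrom": ("chrom", "CHROM"),
    "pos": ("pos", "POS"),
    "ref": ("ref", "REF"),
    "alt": ("alt", "ALT"),
}
_AMP_CA_ALIASES = {
    "id": ("id", "amplicon_id", "amplicon"),
    "chrom": ("chrom", "CHROM"),
    "start": ("start", "start_pos"),
    "end": ("end", "end_pos"),
}


def _decode(arr) -> list[str]:
    return [x.decode() if isinstance(x, bytes) else str(x) for x in np.asarray(arr)]


def _find(group: h5py.Group, aliases: tuple[str, ...], context: str):
    for name in aliases:
        if name in group:
            return group[name]
    raise SchemaError(f"missing dataset {context}/{aliases[0]}")


def _require(f: h5py.File, path: str):
    if path not in f:
        raise SchemaError(f"missing required group/dataset: {path}")
    return f[path]


def read_h5(path: PathLike) -> ScdnaDataset:
    """Load one Tapestri-style ``.h5`` file into memory.

    Calls with ``DP == 0`` are canonicalized to ``AF = 0``, ``NGT = 3``
    (missing); the number of coerced calls is recorded in
    ``run_metadata["n_calls_coerced_missing"]``.

    Raises
    ------
    SchemaError
        if a required group or dataset is absent, naming the missing path.
    ConsistencyError
        if matrix dimensions disagree across layers.
    """
    with h5py.File(path, "r") as f:
        rc_grp = _require(f, "assays/dna_read_counts")
        counts = np.asarray(_require(f, "assays/dna_read_counts/layers/read_counts"))
        amp_ca = _require(f, "assays/dna_read_counts/ca")
        amp_ids = _decode(_find(amp_ca, _AMP_CA_ALIASES["id"], rc_grp.name + "/ca"))
        amp_chrom = _decode(_find(amp_ca, _AMP_CA_ALIASES["chrom"], rc_grp.name + "/ca"))
        amp_start = np.asarray(_find(amp_ca, _AMP_CA_ALIASES["start"], rc_grp.name + "/ca"), dtype=int)
        amp_end = np.asarray(_find(amp_ca, _AMP_CA_ALIASES["end"], rc_grp.name + "/ca"), dtype=int)

        var_grp = _require(f, "assays/dna_variants")
        layers = _require(f, "assays/dna_variants/layers")
        mats = {}
        for name in _VARIANT_LAYERS:
            if name not in layers:
                raise SchemaError(
                    f"missing required group/dataset: assays/dna_variants/layers/{name}"
                )
            mats[name] = np.asarray(layers[name])
        var_ca = _require(f, "assays/dna_variants/ca")
        chrom = _decode(_find(var_ca, _CA_ALIASES["chrom"], var_grp.name + "/ca"))
        pos = np.asarray(_find(var_ca, _CA_ALIASES["pos"], var_grp.name + "/ca"), dtype=int)
        ref = _decode(_find(var_ca, _CA_ALIASES["ref"], var_grp.name + "/ca"))
        alt = _decode(_find(var_ca, _CA_ALIASES["alt"], var_grp.name + "/ca"))
        barcodes = _decode(_require(f, "assays/dna_variants/ra/barcode"))

        metadata: dict[str, str] = {}
        if "metadata" in f:
            for key, ds in f["metadata"].items():
                val = ds[()]
                metadata[key] = val.decode() if isinstance(val, bytes) else str(val)

    n = len(barcodes)
    v = len(chrom)
    a = len(amp_ids)
    if counts.shape != (n, a):
        raise ConsistencyError(
            f"read_counts shape {counts.shape} does not match "
            f"(cells, amplicons) = ({n}, {a})"
        )
    for name, m in mats.items():
        if m.shape != (n, v):
            raise ConsistencyError(
                f"layer {name} shape {m.shape} does not match "
                f"(cells, variants) = ({n}, {v})"
            )

    af = mats["AF"].astype(float)
    dp = mats["DP"].astype(np.int64)
    gq = mats["GQ"].astype(np.int64)
    ngt = mats["NGT"].astype(np.int64)

    # canonicalize missing data: depth-0 calls carry no information
    zero_dp = dp == 0
    n_coerced = int((zero_dp & ((ngt != 3) | (af != 0))).sum())
    af[zero_dp] = 0.0
    ngt[zero_dp] = 3

    amplicons = [
        Amplicon(amplicon_id=i, chrom=c, start=int(s), end=int(e))
        for i, c, s, e in zip(amp_ids, amp_chrom, amp_start, amp_end)
    ]
    variants = [
        Variant(chrom=c, pos=int(p), ref=r, alt=t)
        for c, p, r, t in zip(chrom, pos, ref, alt)
    ]
    ds = ScdnaDataset(
        cell_barcodes=barcodes,
        amplicons=amplicons,
        variants=variants,
        read_counts=counts.astype(np.int64),
        af=af,
        dp=dp,
        gq=gq,
        ngt=ngt,
        run_metadata=metadata,
    )
    ds.n_calls_coerced_missing = n_coerced
    ds.check_invariants()
    return ds


def write_h5(dataset: ScdnaDataset, path: PathLike) -> None:
    """Write a dataset to the fixed schema; refuses invariant violations."""
    violations = dataset.invariant_violations()
    if violations:
        raise ConsistencyError(
            "refusing to write invalid dataset: " + "; ".join(violations)
        )
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        rc = f.create_group("assays/dna_read_counts")
        rc.create_dataset("layers/read_counts", data=dataset.read_counts.astype(np.int64))
        ca = rc.create_group("ca")
        ca.create_dataset("id", data=[a.amplicon_id for a in dataset.amplicons], dtype=str_dt)
        ca.create_dataset("chrom", data=[a.chrom for a in dataset.amplicons], dtype=str_dt)
        ca.create_dataset("start", data=np.array([a.start for a in dataset.amplicons], dtype=np.int64))
        ca.create_dataset("end", data=np.array([a.end for a in dataset.amplicons], dtype=np.int64))

        var = f.create_group("assays/dna_variants")
        layers = var.create_group("layers")
        layers.create_dataset("AF", data=dataset.af.astype(np.float64))
        layers.create_dataset("DP", data=dataset.dp.astype(np.int64))
        layers.create_dataset("GQ", data=dataset.gq.astype(np.int64))
        layers.create_dataset("NGT", data=dataset.ngt.astype(np.int64))
        vca = var.create_group("ca")
        vca.create_dataset("chrom", data=[v.chrom for v in dataset.variants], dtype=str_dt)
        vca.create_dataset("pos", data=np.array([v.pos for v in dataset.variants], dtype=np.int64))
        vca.create_dataset("ref", data=[v.ref for v in dataset.variants], dtype=str_dt)
        vca.create_dataset("alt", data=[v.alt for v in dataset.variants], dtype=str_dt)
        var.create_dataset("ra/barcode", data=dataset.cell_barcodes, dtype=str_dt)

        meta = f.create_group("metadata")
        for key, value in dataset.run_metadata.items():
            meta.create_dataset(key, data=str(value), dtype=str_dt)


_REQUIRED_PATHS = (
    "assays/dna_read_counts/layers/read_counts",
    "assays/dna_read_counts/ca",
    "assays/dna_variants/layers/AF",
    "assays/dna_variants/layers/DP",
    "assays/dna_variants/layers/GQ",
    "assays/dna_variants/layers/NGT",
    "assays/dna_variants/ca",
    "assays/dna_variants/ra/barcode",
)


def validate_h5(path: PathLike) -> ValidationReport:
    """Check a readable ``.h5`` file against the schema and data invariants.

    Never raises on a merely invalid file: each problem becomes a failed
    check in the report.  An unreadable file still raises ``OSError``.
    """
    report = ValidationReport()
    with h5py.File(path, "r") as f:
        missing = [p for p in _REQUIRED_PATHS if p not in f]
        report.add(
            "required_paths",
            not missing,
            "all present" if not missing else "missing: " + ", ".join(missing),
        )
        if missing:
            return report

        barcodes = _decode(f["assays/dna_variants/ra/barcode"])
        n = len(barcodes)
        counts = np.asarray(f["assays/dna_read_counts/layers/read_counts"])
        try:
            var_ca = f["assays/dna_variants/ca"]
            chrom = _decode(_find(var_ca, _CA_ALIASES["chrom"], "ca"))
            pos = np.asarray(_find(var_ca, _CA_ALIASES["pos"], "ca"), dtype=int)
            ref = _decode(_find(var_ca, _CA_ALIASES["ref"], "ca"))
            alt = _decode(_find(var_ca, _CA_ALIASES["alt"], "ca"))
        except SchemaError as e:
            report.add("required_paths", False, str(e))
            return report
        v = len(chrom)

        shapes_ok = counts.ndim == 2 and counts.shape[0] == n
        msgs = []
        if not shapes_ok:
            msgs.append(f"read_counts shape {counts.shape} vs {n} cells")
        layers = {}
        for name in _VARIANT_LAYERS:
            m = np.asarray(f[f"assays/dna_variants/layers/{name}"])
            layers[name] = m
            if m.shape != (n, v):
                shapes_ok = False
                msgs.append(f"{name} shape {m.shape} vs expected ({n}, {v})")
        report.add("shape_consistency", shapes_ok, "; ".join(msgs) or "consistent")

        ngt = layers["NGT"]
        ngt_ok = bool(np.isin(ngt, (0, 1, 2, 3)).all())
        bad_vals = [] if ngt_ok else np.unique(ngt[~np.isin(ngt, (0, 1, 2, 3))]).tolist()
        report.add(
            "ngt_codes",
            ngt_ok,
            "codes in {0,1,2,3}" if ngt_ok else f"invalid NGT values: {bad_vals}",
        )
        af = layers["AF"]
        af_ok = bool(((af >= 0) & (af <= 100)).all()) if af.size else True
        report.add("af_range", af_ok, "AF in [0,100]" if af_ok else "AF outside [0,100]")
        nonneg_ok = True
        nn_msgs = []
        for name, m in (("DP", layers["DP"]), ("GQ", layers["GQ"]), ("read_counts", counts)):
            if m.size and (np.asarray(m) < 0).any():
                nonneg_ok = False
                nn_msgs.append(name)
        report.add(
            "nonnegative_layers",
            nonneg_ok,
            "DP/GQ/read_counts non-negative" if nonneg_ok
            else "negative values in: " + ", ".join(nn_msgs),
        )
        bc_ok = len(set(barcodes)) == n
        report.add("unique_barcodes", bc_ok, "" if bc_ok else "duplicate cell barcodes")
        keys = list(zip(chrom, pos.tolist(), ref, alt))
        key_ok = len(set(keys)) == v
        report.add("unique_variant_keys", key_ok, "" if key_ok else "duplicate variant keys")
    return report
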