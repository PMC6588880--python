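"""Readers and writers: PDB/mmCIF structures, TSV tables, JSON outputs.

TSV dialects
------------
Hit table: ``chain_id  ref_domain_id  q_intervals  ref_length  ref_coverage
score`` with ``q_intervals`` a comma-separated list of ``start-end`` pairs.

Chain metadata: ``chain_id  length  unknown_runs  tm_runs  method
synthetic`` where the run columns are ``start-end`` lists (``-`` if empty)
and synthetic is 0/1.

TM ranges: ``chain_id  seg_index  start  end  is_core  is_coupling``.

JSON outputs carry a top-level ``schema_version`` field.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .geometry import (ChainCoords, MembraneFrame, Orientation, TMProfile,
                       TMSegment, default_frame)
from .intervals import (ResidueInterval, format_interval_list,
                        parse_interval_list)
from .partition import (AlignmentHit, ChainRecord, CurationSummary, Method,
                        PartitionResult, SUMMARY_CATEGORIES)

SCHEMA_VERSION = "1"


# --------------------------------------------------------------------------
# structures
# --------------------------------------------------------------------------

def read_structure(path: str | Path,
                   chain_id: Optional[str] = None) -> ChainCoords:
    """Ordered Cα coordinates (residue number, xyz) for one chain.

    Reads PDB or mmCIF (auto-detected), first model only, preferring
    altloc '' or 'A'.  With ``chain_id`` None the file must contain a
    single chain.  Raises ValueError for a missing chain or a chain with
    no Cα atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    names = [ch.name for ch in model]
    if chain_id is None:
        if len(names) != 1:
            raise ValueError(f"{path}: multiple chains {names}; "
                             "specify a chain id")
        chain_id = names[0]
    chain = None
    for ch in model:
        if ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        raise ValueError(f"{path}: chain {chain_id!r} not found "
                         f"(available: {names})")
    coords: list[tuple[int, np.ndarray]] = []
    for res in chain:
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("", "A", "\0"):
                pos = atom.pos
                coords.append((res.seqid.num,
                               np.array([pos.x, pos.y, pos.z])))
                break
    if not coords:
        raise ValueError(f"{path}: chain {chain_id!r} has no Cα atoms")
    coords.sort(key=lambda t: t[0])
    return coords


def write_structure(chain_coords: ChainCoords, path: str | Path,
                    chain_id: str = "A", name: str = "synthetic") -> None:
    """Write Cα-only coordinates as PDB or mmCIF (chosen by suffix)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model(1)
    chain = gemmi.Chain(chain_id)
    for resnum, xyz in chain_coords:
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(resnum), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*map(float, xyz))
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# --------------------------------------------------------------------------
# TSV tables
# --------------------------------------------------------------------------

def read_hits_tsv(path: str | Path) -> dict[str, list[AlignmentHit]]:
    """Alignment hits per chain id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chain_id", "ref_domain_id", "q_intervals", "ref_length",
                "ref_coverage", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[AlignmentHit]] = {}
    for row in df.itertuples(index=False):
        hit = AlignmentHit(
            ref_domain_id=row.ref_domain_id,
            query_intervals=parse_interval_list(row.q_intervals),
            ref_length=int(row.ref_length),
            ref_coverage=float(row.ref_coverage),
            score=float(row.score))
        out.setdefault(row.chain_id, []).append(hit)
    return out


def write_hits_tsv(hits_by_chain: dict[str, Sequence[AlignmentHit]],
                   path: str | Path) -> None:
    rows = []
    for chain_id, hits in hits_by_chain.items():
        for h in hits:
            rows.append({
                "chain_id": chain_id,
                "ref_domain_id": h.ref_domain_id,
                "q_intervals": format_interval_list(h.query_intervals),
                "ref_length": h.ref_length,
                "ref_coverage": f"{h.ref_coverage:g}",
                "score": f"{h.score:g}",
            })
    pd.DataFrame(rows, columns=["chain_id", "ref_domain_id", "q_intervals",
                                "ref_length", "ref_coverage", "score"]) \
        .to_csv(path, sep="\t", index=False)


def read_chains_tsv(path: str | Path) -> dict[str, ChainRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chain_id", "length", "unknown_runs", "tm_runs", "method",
                "synthetic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, ChainRecord] = {}
    for row in df.itertuples(index=False):
        mask = frozenset(r for iv in parse_interval_list(row.unknown_runs)
                         for r in iv.residues())
        out[row.chain_id] = ChainRecord(
            chain_id=row.chain_id,
            length=int(row.length),
            unknown_mask=mask,
            tm_annotations=tuple(sorted(parse_interval_list(row.tm_runs))),
            method=Method[row.method],
            synthetic_flag=row.synthetic.strip() in {"1", "true", "True"})
    return out


def write_chains_tsv(chains: Sequence[ChainRecord], path: str | Path) -> None:
    from .intervals import intervals_from_residues
    rows = []
    for c in chains:
        rows.append({
            "chain_id": c.chain_id,
            "length": c.length,
            "unknown_runs": format_interval_list(
                intervals_from_residues(c.unknown_mask)),
            "tm_runs": format_interval_list(c.tm_annotations),
            "method": c.method.value,
            "synthetic": int(c.synthetic_flag),
        })
    pd.DataFrame(rows, columns=["chain_id", "length", "unknown_runs",
                                "tm_runs", "method", "synthetic"]) \
        .to_csv(path, sep="\t", index=False)


def read_tm_ranges_tsv(path: str | Path
                       ) -> dict[str, tuple[list[ResidueInterval],
                                            list[bool], list[bool]]]:
    """Per-chain TM ranges with core/coupling flags, in file order."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chain_id", "seg_index", "start", "end", "is_core",
                "is_coupling"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, tuple[list[ResidueInterval], list[bool], list[bool]]] = {}
    for row in df.itertuples(index=False):
        ranges, core, coupling = out.setdefault(row.chain_id, ([], [], []))
        ranges.append(ResidueInterval(int(row.start), int(row.end)))
        core.append(row.is_core.strip() in {"1", "true", "True"})
        coupling.append(row.is_coupling.strip() in {"1", "true", "True"})
    return out


def write_tm_ranges_tsv(ranges: Sequence[ResidueInterval],
                        path: str | Path,
                        chain_id: str = "A",
                        is_core: Sequence[bool] | None = None,
                        is_coupling: Sequence[bool] | None = None) -> None:
    n = len(ranges)
    core = list(is_core) if is_core is not None else [True] * n
    coupling = list(is_coupling) if is_coupling is not None else [False] * n
    rows = [{
        "chain_id": chain_id, "seg_index": i + 1,
        "start": iv.start, "end": iv.end,
        "is_core": int(core[i]), "is_coupling": int(coupling[i]),
    } for i, iv in enumerate(ranges)]
    pd.DataFrame(rows, columns=["chain_id", "seg_index", "start", "end",
                                "is_core", "is_coupling"]) \
        .to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# JSON outputs
# --------------------------------------------------------------------------

def partition_result_to_dict(result: PartitionResult,
                             chain: ChainRecord) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "chain_id": result.chain_id,
        "chain_length": chain.length,
        "method": chain.method.value,
        "outcome": result.outcome.value,
        "reasons": sorted(r.value for r in result.reasons),
        "architecture_tags": sorted(t.value for t in
                                    result.architecture_tags),
        "covered_frac": round(result.covered_frac, 6),
        "conflict": result.conflict,
        "assignments": [{
            "ref_domain_id": a.ref_domain_id,
            "query_intervals": [str(iv) for iv in a.query_intervals],
            "trimmed_residues": a.trimmed_residues,
            "score": a.source_hit.score,
        } for a in result.assignments],
        "gaps": [str(g) for g in result.gaps],
    }


def write_partition_json(result: PartitionResult, chain: ChainRecord,
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(partition_result_to_dict(result, chain), fh, indent=2,
                  sort_keys=True)
        fh.write("\n")


def profile_to_dict(profile: TMProfile,
                    handedness: Optional[str] = None) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "label": profile.label,
        "frame": {
            "normal": [round(float(x), 9) for x in profile.frame.normal],
            "origin": [round(float(x), 6) for x in profile.frame.origin],
        },
        "segments": [{
            "index": s.index,
            "interval": str(s.interval),
            "axis": [round(float(x), 9) for x in s.axis],
            "centroid": [round(float(x), 6) for x in s.centroid],
            "orientation": s.orientation.value,
            "is_core": s.is_core,
            "is_coupling_helix": s.is_coupling_helix,
        } for s in profile.segments],
        **({"handedness": handedness} if handedness is not None else {}),
    }


def write_profile_json(profile: TMProfile, path: str | Path,
                       handedness: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        json.dump(profile_to_dict(profile, handedness), fh, indent=2,
                  sort_keys=True)
        fh.write("\n")


def read_profile_json(path: str | Path) -> TMProfile:
    with open(path) as fh:
        data = json.load(fh)
    frame = MembraneFrame(np.array(data["frame"]["normal"], dtype=float),
                          np.array(data["frame"]["origin"], dtype=float))
    segs = tuple(TMSegment(
        index=s["index"],
        interval=ResidueInterval.parse(s["interval"]),
        axis=np.array(s["axis"], dtype=float),
        centroid=np.array(s["centroid"], dtype=float),
        orientation=Orientation[s["orientation"]],
        is_core=s["is_core"],
        is_coupling_helix=s["is_coupling_helix"],
    ) for s in data["segments"])
    return TMProfile(segments=segs, frame=frame,
                     label=data.get("label", ""))


def write_summary_tsv(summary: CurationSummary, path: str | Path) -> None:
    rows = [{"category": "total_chains", "count": summary.total_chains,
             "percent": 100}]
    rows += [{"category": cat, "count": summary.counts[cat],
              "percent": summary.percentages[cat]}
             for cat in SUMMARY_CATEGORIES]
    pd.DataFrame(rows, columns=["category", "count", "percent"]) \
        .to_csv(path, sep="\t", index=False)
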