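"""Serialization: transition tallies, profiles, flux reports, run configs.

Counts are written as a delimited-text matrix (states named ``start``,
``d000``..``dNNN``, ``escape``) plus a JSON sidecar holding the
configuration, the body and source specifications, the subsample blocks and
the block seeds — enough to re-run the simulation bitwise-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Body, DomainPartition, domain_partition, make_body
from .markov import AbsorptionResult, ReactivityProfile
from .wos import SimulationConfig, SourceSpec, TransitionCounts

SCHEMA_VERSION = 1


def write_counts(tc: TransitionCounts, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.tsv`` (pooled matrix) and ``<stem>.json`` (sidecar)."""
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    js = stem.with_suffix(".json")
    names = tc.state_names()
    df = pd.DataFrame(tc.counts, index=names, columns=names)
    df.to_csv(tsv, sep="\t", index_label="from")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "M": tc.M, "n_try": tc.n_try, "n_capped": tc.n_capped,
        "n_bad_reflect": tc.n_bad_reflect,
        "config": tc.config, "body": tc.body, "source": tc.source,
        "block_seeds": tc.block_seeds,
        "block_counts": tc.block_counts.tolist(),
        "online": tc.online.tolist() if tc.online is not None else None,
        "online_blocks": (tc.online_blocks.tolist()
                          if tc.online_blocks is not None else None),
    }
    js.write_text(json.dumps(sidecar))
    return tsv, js


def read_counts(stem: str | Path) -> TransitionCounts:
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    js = stem.with_suffix(".json")
    df = pd.read_csv(tsv, sep="\t", index_col=0)
    counts = df.to_numpy(dtype=np.int64)
    side = json.loads(js.read_text())
    blocks = np.asarray(side["block_counts"], dtype=np.int64)
    if not np.array_equal(blocks.sum(axis=0), counts):
        raise ValueError(f"sidecar blocks do not sum to the matrix in {tsv}")
    online = side.get("online")
    online_blocks = side.get("online_blocks")
    return TransitionCounts(
        counts=counts, block_counts=blocks, M=int(side["M"]),
        n_try=int(side["n_try"]), n_capped=int(side["n_capped"]),
        n_bad_reflect=int(side.get("n_bad_reflect", 0)),
        config=side["config"], body=side["body"], source=side["source"],
        block_seeds=list(side.get("block_seeds", [])),
        online=np.asarray(online, dtype=np.int64) if online is not None else None,
        online_blocks=(np.asarray(online_blocks, dtype=np.int64)
                       if online_blocks is not None else None))


def counts_partition(tc: TransitionCounts) -> tuple[Body, DomainPartition]:
    """Rebuild the body and its partition from a counts sidecar."""
    body = Body.from_dict(tc.body)
    return body, domain_partition(body, tc.M)


def read_profile(path: str | Path) -> ReactivityProfile:
    """Read an M-vector reactivity profile from a one-column text file."""
    values = np.loadtxt(path, ndmin=1)
    return ReactivityProfile(values)


def write_profile(profile: ReactivityProfile, path: str | Path) -> None:
    np.savetxt(path, profile.k, fmt="%.17g")


def write_result(result: AbsorptionResult, profile: ReactivityProfile,
                 partition: DomainPartition, stem: str | Path) -> tuple[Path, Path]:
    """Write the per-domain table (tsv) and the scalar summary (json)."""
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    js = stem.with_suffix(".json")
    df = pd.DataFrame({
        "domain": np.arange(partition.M),
        "z_center": partition.band_centers,
        "cos_beta": partition.cos_beta,
        "k": profile.k,
        "f": result.f,
        "absorbed_fraction": result.absorbed_by_domain,
        "local_flux": (result.local_flux if result.local_flux is not None
                       else np.zeros(partition.M)),
    })
    df.to_csv(tsv, sep="\t", index=False, float_format="%.17g")
    summary = {
        "K": profile.mean,
        "P_A": result.P_A,
        "phi_total": result.phi_total,
        "phi_smoluchowski": result.phi_smoluchowski,
        "units_note": result.units_note,
    }
    js.write_text(json.dumps(summary, indent=2))
    return tsv, js


# -- run configuration -----------------------------------------------------

def run_config_to_yaml(body_kind: str, body_parameter: float | None,
                       config: SimulationConfig, source: SourceSpec,
                       path: str | Path) -> None:
    doc = {"schema_version": SCHEMA_VERSION,
           "body": {"shape_kind": body_kind, "parameter": body_parameter},
           "config": config.to_dict(), "source": source.to_dict()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def run_config_from_yaml(path: str | Path):
    doc = yaml.safe_load(Path(path).read_text())
    body = make_body(doc["body"]["shape_kind"], doc["body"].get("parameter"))
    config = SimulationConfig.from_dict(doc["config"])
    source = SourceSpec.from_dict(doc["source"])
    return body, config, source
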