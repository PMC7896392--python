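"""Versioned profile archive: a zip of JSON members with a manifest.

Floats survive the JSON round trip exactly (repr-based encoding), so
``load(save(p))`` reproduces every model bit-identically; a schema-version
mismatch is detected and reported on load.
"""

from __future__ import annotations

import json
import zipfile

import numpy as np

from .adapters import AdapterSet
from .covmodel import CombinedBias, Dispersion, FlankParams
from .margins import PairwiseExpModel
from .sim import DegenerateSampler, Sampler, SimProfile

SCHEMA_VERSION = 1


def _sampler_to_dict(s) -> dict:
    if isinstance(s, DegenerateSampler):
        return {"degenerate": int(s.value)}
    return {"nominal": s.nominal, "model": s.model.to_dict()}


def _sampler_from_dict(d):
    if "degenerate" in d:
        return DegenerateSampler(d["degenerate"])
    return Sampler(PairwiseExpModel.from_dict(d["model"]), d["nominal"])


def save_profile(profile: SimProfile, path, seed: int | None = None) -> None:
    members: dict[str, dict] = {}
    members["manifest.json"] = {
        "schema_version": SCHEMA_VERSION,
        "tool": "readsmith",
        "seed": seed,
        "read_length": profile.read_length,
        "tiles": profile.tiles,
        "max_qual": profile.max_qual,
        "tendency_alphabet": profile.tendency_alphabet,
    }
    c = profile.combined
    members["coverage.json"] = {
        "flank": c.flank.table.tolist(),
        "gc_bias": np.asarray(c.gc_bias).tolist(),
        "alpha": c.dispersion.alpha,
        "beta": c.dispersion.beta,
        "b_ref": c.b_ref,
        "b_len": {str(k): v for k, v in c.b_len.items()},
    }
    members["fragment_lengths.json"] = {
        str(k): v for k, v in profile.fragment_length_distribution.items()
    }
    if profile.adapter_set is not None:
        members["adapters.json"] = {
            "first": profile.adapter_set.first,
            "second": profile.adapter_set.second,
            "pairing": profile.adapter_set.pairing.astype(int).tolist(),
        }
    for name in ("tendency", "rate", "seq_quality", "indel"):
        members[f"sampler_{name}.json"] = _sampler_to_dict(
            profile.samplers[name]
        )
    members["indel_active.json"] = {
        "active": bool(profile.samplers.get("indel_active", False))
    }
    for group in ("base_quality", "base_call"):
        for (seg, tile, rb), s in profile.samplers[group].items():
            members[f"sampler_{group}.{seg}.{tile}.{rb}.json"] = \
                _sampler_to_dict(s)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, payload in members.items():
            zf.writestr(name, json.dumps(payload))


def load_profile(path) -> SimProfile:
    with zipfile.ZipFile(path) as zf:
        members = {n: json.loads(zf.read(n)) for n in zf.namelist()}
    manifest = members["manifest.json"]
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"profile schema version {manifest.get('schema_version')} "
            f"does not match supported version {SCHEMA_VERSION}"
        )
    cov = members["coverage.json"]
    combined = CombinedBias(
        FlankParams(np.array(cov["flank"])),
        np.array(cov["gc_bias"]),
        Dispersion(cov["alpha"], cov["beta"]),
        dict(cov["b_ref"]),
        {int(k): v for k, v in cov["b_len"].items()},
    )
    adapter_set = None
    if "adapters.json" in members:
        a = members["adapters.json"]
        adapter_set = AdapterSet(a["first"], a["second"],
                                 np.array(a["pairing"], dtype=bool))
    samplers: dict = {}
    for name in ("tendency", "rate", "seq_quality", "indel"):
        samplers[name] = _sampler_from_dict(members[f"sampler_{name}.json"])
    samplers["indel_active"] = members.get(
        "indel_active.json", {"active": False})["active"]
    for group in ("base_quality", "base_call"):
        d = {}
        prefix = f"sampler_{group}."
        for name, payload in members.items():
            if name.startswith(prefix):
                seg, tile, rb = name[len(prefix):-5].split(".")
                d[(int(seg), int(tile), int(rb))] = _sampler_from_dict(payload)
        samplers[group] = d
    return SimProfile(
        combined=combined,
        samplers=samplers,
        fragment_length_distribution={
            int(k): v for k, v in members["fragment_lengths.json"].items()
        },
        adapter_set=adapter_set,
        read_length=manifest["read_length"],
        tiles=manifest["tiles"],
        max_qual=manifest["max_qual"],
        tendency_alphabet=manifest["tendency_alphabet"],
    )
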