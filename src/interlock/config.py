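"""Plain-text run configuration (INI-style sections, strict keys).

Unknown sections or keys are rejected outright: a silently ignored typo in
a threshold name would corrupt the analysis semantics.  Defaults follow the
conventional values of each stage (gap filter 0.30, I_min 2.5, stability
0.5, H-bond occupancy threshold 0.5, snapshot stride 1).
"""

from __future__ import annotations

import configparser
import hashlib
import io
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig", "ConfigError", "parse_config", "load_config", "demo_config"]


class ConfigError(ValueError):
    pass


#: every allowed key with its default (as text); None marks "no default,
#: optional" — section presence itself is optional
SCHEMA: dict[str, dict[str, str | None]] = {
    "run": {
        "seed": "0",
        "stages": "simulate,coevolve,psn,interface,metrics",
    },
    "inputs": {
        "msa_a": None,
        "msa_b": None,
        "ensemble": None,
        "reference": None,
    },
    "synthetic": {
        "n_seqs": "100",
        "length_a": "25",
        "length_b": "25",
        "couplings": "8,40,0.9",  # i,j,strength triples separated by ';'
        "gap_fraction": "0.05",
        "n_res_a": "30",
        "n_res_b": "20",
        "contact_pairs": "4,6;8,10;12,14",
        "hbond_pairs": "8,10",
        "path_chain": "18,21,24,27",
        "n_frames": "10",
        "noise_sd": "0.05",
        "broken_fraction": "0.3",
    },
    "coevolution": {
        "a": "0.05",
        "b": "10.0",
        "top_n": "24",
        "max_gap_fraction": "0.30",
        "min_separation": "5",
        "weighted": "false",
    },
    "network": {
        "contact_cutoff": "4.5",
        "i_min": "2.5",
        "auto_imin": "false",
        "exclude_neighbors": "2",
        "stability": "0.5",
        "consensus_fraction": "0.5",
        "sources": "A18",
        "sink": "A27",
    },
    "interface": {
        "chain_a": "A",
        "chain_b": "B",
        "da_cutoff": "3.5",
        "angle_cutoff": "30.0",
        "e_hb": "-1.5",
        "e_elec": "1.0",
        "elec_cutoff": "6.0",
        "e_vdw": "-0.2",
        "vdw_lo": "3.0",
        "vdw_hi": "5.0",
        "interface_cutoff": "5.0",
        "hotspot_threshold": "-2.0",
        "stride": "1",
    },
    "metrics": {
        "selection": "backbone",
        "rmsf_window": "0.5",
    },
}


@dataclass
class RunConfig:
    values: dict[str, dict[str, str]]
    sha256: str

    def get(self, section: str, key: str) -> str | None:
        return self.values[section][key]

    def get_str(self, section: str, key: str) -> str:
        v = self.values[section][key]
        if v is None:
            raise ConfigError(f"[{section}] {key} is required but not set")
        return v

    def get_float(self, section: str, key: str) -> float:
        return float(self.get_str(section, key))

    def get_int(self, section: str, key: str) -> int:
        return int(self.get_str(section, key))

    def get_bool(self, section: str, key: str) -> bool:
        v = self.get_str(section, key).lower()
        if v in ("true", "yes", "1", "on"):
            return True
        if v in ("false", "no", "0", "off"):
            return False
        raise ConfigError(f"[{section}] {key}: cannot parse {v!r} as boolean")

    def get_list(self, section: str, key: str) -> list[str]:
        v = self.get(section, key)
        return [x.strip() for x in v.split(",") if x.strip()] if v else []

    def stages(self) -> list[str]:
        return self.get_list("run", "stages")


def parse_residue_id(text: str) -> tuple[str, int, str]:
    """'A18' or 'B5a' -> (chain, number, insertion_code)."""
    text = text.strip()
    if len(text) < 2:
        raise ConfigError(f"cannot parse residue id {text!r}")
    chain, rest = text[0], text[1:]
    icode = ""
    if rest and rest[-1].isalpha():
        rest, icode = rest[:-1], rest[-1]
    try:
        return (chain, int(rest), icode)
    except ValueError:
        raise ConfigError(f"cannot parse residue id {text!r}") from None


def parse_pair_list(text: str) -> list[tuple[int, int]]:
    """'4,6;8,10' -> [(4, 6), (8, 10)]."""
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        a, b = chunk.split(",")
        out.append((int(a), int(b)))
    return out


def parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.split(",") if x.strip()]


def parse_config(text: str) -> RunConfig:
    parser = configparser.ConfigParser(interpolation=None)
    try:
        parser.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse config: {exc}") from exc
    values: dict[str, dict[str, str]] = {
        section: dict(defaults) for section, defaults in SCHEMA.items()
    }
    for section in parser.sections():
        if section not in SCHEMA:
            raise ConfigError(f"unknown config section [{section}]")
        for key, value in parser.items(section):
            if key not in SCHEMA[section]:
                raise ConfigError(f"unknown key {key!r} in section [{section}]")
            values[section][key] = value
    sha = hashlib.sha256(text.encode()).hexdigest()
    return RunConfig(values=values, sha256=sha)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return parse_config(path.read_text())


def demo_config(seed: int = 0) -> str:
    """Self-contained demo configuration over synthetic inputs.

    Toy pseudo-residues carry only 2-4 heavy atoms (real residues average
    around 8), so interaction strengths are proportionally lower; the demo
    therefore analyses the toy complex at I_min = 1.0 while the package
    default for real structures stays at 2.5.
    """
    return f"""\
[run]
seed = {seed}
stages = simulate,coevolve,psn,interface,metrics

[synthetic]
n_seqs = 100
length_a = 25
length_b = 25
couplings = 8,40,0.9
gap_fraction = 0.05
n_res_a = 30
n_res_b = 20
contact_pairs = 4,6;8,10;12,14
hbond_pairs = 8,10
path_chain = 18,21,24,27
n_frames = 10
noise_sd = 0.05
broken_fraction = 0.3

[coevolution]
top_n = 24

[network]
i_min = 1.0
sources = A18
sink = A27

[interface]
chain_a = A
chain_b = B

[metrics]
rmsf_window = 0.5
"""
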