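"""Worked example: monomeric Cereblon (CRBN) versus its dimer-bound copies.

CRBN binds IMiD-class molecular glues (thalidomide analogues) in a pocket
that sits adjacent to the interface it forms with neosubstrates.  The
monomeric structure 8RQ8 (chain A) superposes onto the CRBN copies found
in several glue-bound dimers with low Calpha RMSD, which is why a
monomer-derived ligand pose can be transferred into the dimer context.

Requires network access to fetch mmCIF files from the PDB (or a directory
of pre-downloaded files passed with --cache).

Usage: python scripts/crbn_superposition.py [--cache DIR]
"""

import argparse
import urllib.request
from pathlib import Path

MONOMER = ("8rq8", "A")
DIMERS = [
    ("4ci1", "B"),
    ("8oiz", "B"),
    ("8g66", "B"),
    ("5fqd", "B"),
    ("5hxb", "C"),
    ("6h0g", "B"),
    ("8u16", "A"),
]
RMSD_BOUND = 2.1  # Angstrom


def fetch(pdb_id: str, cache: Path, timeout: float = 15.0) -> Path:
    cache.mkdir(parents=True, exist_ok=True)
    path = cache / f"{pdb_id}.cif"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.cif"
        with urllib.request.urlopen(url, timeout=timeout) as response:
            path.write_bytes(response.read())
    return path


def monomer_dimer_rmsds(cache: Path, timeout: float = 15.0) -> dict[str, float]:
    from gluefinder import read_structure
    from gluefinder.pocket_align import chain_superposition_rmsd

    mono = read_structure(
        fetch(MONOMER[0], cache, timeout), assembly_policy="asymmetric_unit"
    )
    mono_chain = mono.chain(MONOMER[1])
    out = {}
    for pdb_id, chain_id in DIMERS:
        model = read_structure(
            fetch(pdb_id, cache, timeout), assembly_policy="asymmetric_unit"
        )
        out[f"{pdb_id}{chain_id}"] = chain_superposition_rmsd(
            mono_chain, model.chain(chain_id)
        )
    return out


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cache", type=Path, default=Path("scratch/pdb_cache"))
    args = parser.parse_args()
    rmsds = monomer_dimer_rmsds(args.cache)
    for name, rmsd in rmsds.items():
        flag = "ok" if rmsd <= RMSD_BOUND else "ABOVE BOUND"
        print(f"8rq8A vs {name}: {rmsd:.2f} A  [{flag}]")
    print(f"max: {max(rmsds.values()):.2f} A (bound {RMSD_BOUND} A)")


if __name__ == "__main__":
    main()
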