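import numpy as np
import pytest

from gluefinder import fixtures as fx


@pytest.fixture(scope="session")
def dimer_model():
    """Standard two-chain fixture: 6 planted contacts, an IAP ligand (6/5
    contacts), a single-chain ligand, and 3 waters."""
    spec = fx.DimerSpec(
        residues_per_chain=30,
        contacts=6,
        ligands=[fx.PlantedLigand("AAA", 6, 5), fx.PlantedLigand("BBB", 5, 0)],
        n_waters=3,
        seed=1,
    )
    return fx.make_dimer_fixture(spec)


@pytest.fixture(scope="session")
def cavity_125():
    return fx.make_cavity_fixture((5.0, 5.0, 5.0))


@pytest.fixture(scope="session")
def glue_case():
    """A cage-dimer target with planted native ligand plus its remote
    homolog template model (identity ~0.25, noise 0.5 A)."""
    target, truth = fx.make_glue_complex(seed=100, ligand_code="LG0", entry_id="TGT0")
    rng = np.random.default_rng(555)
    homolog, hom_truth = fx.make_homolog(
        target,
        mutation_rate=0.75,
        noise_sigma=0.5,
        transform=fx.random_transform(rng),
        seed=556,
        entry_id="TPL0",
    )
    return target, truth, homolog, hom_truth


def brute_force_contact_map(chain_a, chain_b, cutoff):
    """O(n^2) all-pairs oracle for residue-residue contacts."""
    out = {}
    for ra in chain_a.residues:
        xa = ra.heavy_coords()
        for rb in chain_b.residues:
            xb = rb.heavy_coords()
            d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(-1)).min()
            if d <= cutoff:
                out[(ra.key, rb.key)] = float(d)
    return out


def brute_force_ligand_contacts(ligand, chain, cutoff):
    xl = ligand.coords()
    count = 0
    for res in chain.residues:
        xr = res.heavy_coords()
        d = np.sqrt(((xl[:, None, :] - xr[None, :, :]) ** 2).sum(-1)).min()
        if d <= cutoff:
            count += 1
    return count
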