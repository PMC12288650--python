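"""Pool of valid small-molecule SMILES used by the synthetic-corpus generator.

The pool combines a checked-in list of common drug-like structures with a
combinatorial decorator: scaffold templates carrying one attachment point are
expanded against a substituent set.  Building molecules this way (rather than
random string generation) guarantees validity and gives controllable scaffold
overlap — molecules decorated from the same template are Tanimoto-similar,
which the planted-effect tests rely on.
"""

from __future__ import annotations

from functools import lru_cache

from .bioassay_model import canonicalize_smiles, is_valid_smiles

#: common drug-like molecules (family-neutral filler)
BASE_POOL: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",              # aspirin
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",         # ibuprofen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",         # caffeine
    "CC(=O)Nc1ccc(O)cc1",                 # paracetamol
    "Clc1ccccc1",                          # chlorobenzene
    "c1ccc2ccccc2c1",                      # naphthalene
    "c1ccc(-c2ccccc2)cc1",                 # biphenyl
    "OCCN1CCN(C)CC1",
    "O=C1CCCCC1",
    "C1CCNCC1",
    "c1ccncc1",
    "c1ccsc1",
    "c1ccoc1",
    "Cc1ccccc1N",
    "Nc1ccc(O)cc1",
    "OC(=O)c1cccnc1",
    "CCOC(=O)c1ccccc1",
    "CN1CCC(O)CC1",
    "O=C(O)CC(O)(CC(=O)O)C(=O)O",          # citric acid
    "NCCc1ccc(O)c(O)c1",                   # dopamine
    "CC(N)Cc1ccccc1",                      # amphetamine
    "OCC1OC(O)C(O)C(O)C1O",                # glucose
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",       # salbutamol
    "CN(C)CCc1c[nH]c2ccccc12",             # DMT
    "O=c1[nH]cnc2[nH]cnc12",               # hypoxanthine
    "Nc1ncnc2[nH]cnc12",                   # adenine
    "Cc1ncc([N+](=O)[O-])n1CCO",           # metronidazole
    "CSCCC(N)C(=O)O",                      # methionine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",         # tryptophan
    "OC1CCCCC1",
)

#: scaffold templates with one ``{r}`` attachment point, grouped so that
#: different synthetic target families can draw disjoint scaffold subsets
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "O=C(N{r})c1ccccc1",                   # benzamides
    "O=C(N{r})c1ccc(F)cc1",
    "O=C(N{r})c1ccco1",
    "O=C(N{r})c1ccc(Cl)nc1",
    "O=S(=O)(N{r})c1ccc(C)cc1",            # sulfonamides
    "O=S(=O)(N{r})c1ccccc1",
    "{r}Nc1ncccn1",                         # aminopyrimidines
    "{r}Nc1ccnc(N)n1",
    "O=C(N{r})C1CCN(Cc2ccccc2)CC1",        # piperidine amides
    "O=C(N{r})C1CCCN1C",
    "{r}N1CCN(c2ccccn2)CC1",               # piperazines
    "{r}N1CCOCC1",
    "O=C(N{r})c1cc2ccccc2[nH]1",           # indole-2-carboxamides
    "O=C(N{r})c1csc(C)n1",                 # thiazole amides
    "{r}Oc1ccc2ccccc2c1",                  # naphthyl ethers
    "O=C(N{r})Nc1ccccc1",                  # phenylureas
)

SUBSTITUENTS: tuple[str, ...] = (
    "C",
    "CC",
    "CCC",
    "CCO",
    "CCN",
    "CC(C)C",
    "CCOC",
    "C1CCCCC1",
    "Cc1ccccc1",
    "CCc1ccccc1",
    "Cc1ccncc1",
    "CCN(C)C",
    "CC(C)O",
    "CCCC",
)


def decorate(template: str, substituent: str) -> str:
    """Attach a substituent at the template's attachment point."""
    return canonicalize_smiles(template.format(r=substituent))


@lru_cache(maxsize=None)
def scaffold_family_pool(scaffold_indices: tuple[int, ...]) -> tuple[str, ...]:
    """All decorated molecules from the given scaffold templates, canonical and unique."""
    out: list[str] = []
    seen: set[str] = set()
    for i in scaffold_indices:
        for sub in SUBSTITUENTS:
            smiles = decorate(SCAFFOLD_TEMPLATES[i], sub)
            if smiles not in seen:
                seen.add(smiles)
                out.append(smiles)
    return tuple(out)


@lru_cache(maxsize=None)
def full_pool() -> tuple[str, ...]:
    """The complete molecule pool: base list plus every decorated scaffold."""
    out: list[str] = []
    seen: set[str] = set()
    for smiles in BASE_POOL:
        canonical = canonicalize_smiles(smiles)
        if canonical not in seen:
            seen.add(canonical)
            out.append(canonical)
    for smiles in scaffold_family_pool(tuple(range(len(SCAFFOLD_TEMPLATES)))):
        if smiles not in seen:
            seen.add(smiles)
            out.append(smiles)
    assert all(is_valid_smiles(s) for s in out)
    return tuple(out)
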