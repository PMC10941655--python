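# specswitch

Structure-based design of **complex-specificity-switch mutations**.

Many proteins participate in more than one macromolecular complex. The
budding-yeast Tor2 kinase is the canonical case: it assembles with Kog1
into TORC1 and with Avo3 into TORC2, two complexes with different
biological functions. To dissect the role of one complex state without
touching the other, one wants mutations in the shared subunit that abolish
assembly of one complex while preserving the other — a *specificity
switch*.

`specswitch` implements this engineering procedure as a reproducible
desk-scale pipeline:

1. **Model building** — thread the target subunit sequences onto template
   complex structures (alignment-guided backbone grafting), superpose each
   subunit model onto its counterpart in the template (Kabsch/SVD), and
   relieve residual inter-chain clashes by small rigid shifts.
2. **Differential interface** — find residues of the shared subunit whose
   minimum heavy-atom distance to the complex-specific partner (e.g. Kog1)
   is ≤ a contact cutoff *c* in one complex model, while every component of
   the other complex (e.g. Avo3) stays farther than *c* + a safety margin
   in the mapped model:

   ```
   D = { r ∈ shared :  min d(r, partner_in)  ≤ c
                   ∧  ∀p ∈ excluded,  min d(r, p)  >  c + m }
   ```

   Optionally, partner regions absent from orthologues (gap blocks in a
   multiple sequence alignment) are detected, and differential residues
   whose contacts fall inside such species-unique loops are flagged — those
   contacts are the most promising assembly determinants to attack.
3. **Mutation design** — apply simple substitution rules to the
   differential residues: hydrophobic → glutamine (larger, hydrophilic,
   uncharged), and charged residues enlarged with the same charge (K→R,
   D→E). Each proposal is checked geometrically: a soft-sphere overlap
   score `Σ max(0, rᵢ + rⱼ − d)²` of the mutant side chain (small fixed
   χ-rotamer library) against the partner being evicted quantifies the
   designed clash, and relative solvent accessibility of the shared
   subunit alone verifies the new polar surface is exposed. Proposals are
   grouped into sequence regions and all non-empty group unions are
   enumerated as named mutant combinations (K1, K2, K3, K12, …, K123).

A synthetic-fixture generator builds toy helical complexes with planted,
analytically known interfaces, so the entire pipeline is testable with no
structure downloads.

## Worked example

```python
import specswitch as sw

# toy system: shared helix A binds partner B (residues 10-24) in complex 1
# and partner C (residues 20-39) in complex 2
spec = sw.FixtureSpec(seed=7, n_res_focal=50, partner_specs=[
    sw.PartnerSpec("B", (10, 25)), sw.PartnerSpec("C", (20, 40))])
c1, c2, truth = sw.make_two_partner_fixture(spec)

m1 = sw.ComplexModel("m1", c1, {"A": "shared_subunit", "B": "partner_specific"})
m2 = sw.ComplexModel("m2", c2, {"A": "shared_subunit", "C": "partner_specific"})
smap = sw.map_shared_subunit(m1, m2)
diff = sw.differential_interface(m1, m2, smap, "B", ["C"])
print(sorted(diff.residues))
# [10, 11, 12, 13, 14, 15, 16, 17, 18, 19]

design = sw.design_from_differential(m1, diff)
print([p.label for p in design.proposals][:3], "...",
      list(design.combinations))
# ['A10Q', 'A11Q', 'A12Q'] ... ['K1']
```

Residues 10–19 contact partner B but not partner C — exactly the planted
difference of the two footprints. Every target is alanine, so each
proposal follows the hydrophobic-to-glutamine rule, carries a positive
clash score against partner B, and passes the exposure check on the
isolated shared chain.

On a real system the same pipeline is driven by a YAML configuration
naming the two template structures, chain roles, target sequences and an
optional partner-orthologue alignment:

```bash
spec-switch run --config run.yaml
spec-switch diff-interface --complex1 torc1.pdb --complex2 torc2.pdb \
    --shared A --included K --excluded V --cutoff 4.5
spec-switch mutate --positions A740,L742,K768
```

The canonical nine-residue target set of the Tor2 case
(A740, L742, K768, A772, A775, A777, L781, F817, K818) groups into three
sequence regions under the default 10-residue window, giving the seven
named combinations K1, K2, K3, K12, K13, K23, K123.

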