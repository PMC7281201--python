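# Methods

## Scope and model

`cyanogem` implements the constraint-based analysis stack for
photoautotrophic genome-scale metabolic models (GSMMs): a compartmentalized
stoichiometric container with SBML L3/FBC-v2 I/O, biomass-equation
construction from macromolecular composition, FBA and parsimonious FBA under
photoautotrophic constraints, curation checks (biomass-precursor gaps,
thermodynamically infeasible loops, ATP-from-nothing), single-reaction
essentiality, GAM/NGAM sensitivity scanning, and growth-coupled maximum
theoretical yields. All flux units are mmol·(gDCW·h)⁻¹, compositions are
mg per mg dry cell weight, and energy parameters are mmol ATP per gDCW
(GAM) or per gDCW·h (NGAM).

## Biomass equation and degree of reduction

For each macromolecular component with mass fraction w the monomer template
supplies mole fractions x_m and residue formulas (monomer minus condensation
water). The coefficient of monomer m is `1000·w·x_m / M̄` with M̄ the
mole-fraction-weighted residue molar mass, which guarantees mass closure:
Σ coefficient × residue mass = 1000 × Σw mg/gDCW exactly. The growth-
associated maintenance enters as `GAM (ATP + H2O → ADP + Pi)` inside the
biomass reaction; GAM species are excluded from the elemental bookkeeping.

Default monomer templates (shipped as a replaceable YAML):

- protein — average bacterial amino-acid usage (the *E. coli* biomass
  distribution, a standard stand-in where a strain-specific proteome usage
  is unavailable);
- RNA/DNA — equimolar NMP/dNMP residues;
- glycogen and non-glycogen carbohydrate — anhydroglucose units
  (162.14 g/mol);
- lipid — MGDG and PG species with a C16:0/C18:1 acyl profile (70/30),
  reflecting the dominance of these acyls in cyanobacterial thylakoid
  lipids;
- pigments — intact chlorophyll *a* and β-carotene; phycobiliproteins
  follow the protein template.

These templates were fixed from the literature before any comparison with
published biomass formulas and are deliberately not strain-fitted; they are
the main approximation in the biomass arithmetic. Soluble pool, inorganic
ions and peptidoglycan have no default template — the packaged composition
table already sums to 1.02 and a closure warning is raised only beyond
|Σw − 1| > 0.05.

Degree of reduction uses reference states CO2, H2O and a declared nitrogen
reference: weights C=+4, H=+1, O=−2, P=+5, S=+6, and N=−3 (NH3 reference,
the common biomass convention and the default) or N=+5 (NO3⁻ reference).
Published γ values for cyanobacterial biomass do not always state the N
reference; both values are therefore always computable and the CLI reports
both. The photosynthetic-quotient O2 estimate uses the NO3⁻-referenced γ,
because with nitrate as N source the electrons stored per C-mol of biomass
must all originate from water splitting: PQ = γ(NO3)/4.

## Linear programming

All LPs are solved with scipy's HiGHS backend at feasibility/optimality
tolerances of 1e-9, with variables ordered by sorted reaction id — results
are deterministic and order-invariant. pFBA linearizes Σ|v| by the standard
non-negative split v = v⁺ − v⁻ (reversible reactions are doubled internally
and mapped back on output). Every optimal solution is checked against
‖N·v‖∞ ≤ 1e-6 before being returned. The O2-evolution constraint is encoded
as an interval [y−h, y+h] rather than an equality: measured evolution rates
carry meaningful uncertainty and the interval form keeps the growth fixation
feasible across the GAM/NGAM grid.

Because parsimonious optima can be degenerate, the active-reaction count is
reported for the returned solution, and `active_in_any_optimum` exposes
flux-variability ranges at the pFBA optimum (Σ(v⁺+v⁻) ≤ optimum as an extra
row) so downstream counts can be flagged as range-dependent.

Reaction deletion follows the knockout convention: bounds are replaced by
[0, 0] even where a constraint fixed the flux, so deleting the maintenance
pseudo-reaction removes the NGAM demand with it (matching the behaviour of
the standard COBRA tooling, which is also the independent cross-check in the
test suite). The essentiality screen releases a fixed-growth constraint but
keeps the medium, O2 window and NGAM; thresholds are growth ≤ 1e-4 h⁻¹ for
essentiality and |v| ≥ 1e-8 for activity, both configurable.

## Energy parameters

GAM defaults to 53 mmol ATP·gDCW⁻¹ and NGAM to 1.3 mmol·(gDCW·h)⁻¹ — values
adopted in marine *Synechococcus*/*Synechocystis* reconstructions. Neither
is measured for the target strain; both are exposed in
`EnergyParameters` and the sensitivity scan re-solves pFBA over a GAM×NGAM
grid, rebuilding the biomass equation per cell and reporting photon uptake,
O2 evolution, CO2 uptake, total flux and the L1 distance of central-carbon
fluxes from the base solution. Infeasible cells are marked and skipped.

## Curation checks

Gap finding adds a temporary demand per biomass precursor and maximizes it
under the photoautotrophic medium (producible iff max flux > 1e-8); for
gaps, substrates of candidate producing reactions are tested recursively to
name blocking metabolites. The loop test fixes all exchanges to zero and the
ATP synthase flux to a positive value; if feasible, the minimal-total-flux
solution's nonzero reactions are the loop members (minimality keeps the
reported set tight), and the result is invariant to the fixation value. The
ATP-from-nothing test closes all carbon-bearing exchange uptakes and
maximizes maintenance hydrolysis twice — photon closed (any positive flux is
an energy-generating cycle) and photon open (positive flux is expected
photophosphorylation, reported but not flagged). All checks restore bounds
exactly. Directionality repair is supported only as a manual TSV patch file;
no database lookups are performed, keeping runs reproducible.

## Yields

Wild-type growth is the FBA maximum under the same medium (not a measured
rate — the floor is defined relative to what the model itself can do; a flag
allows using a measured rate instead). The product exchange is then
maximized subject to growth ≥ fraction × wild-type (an inequality; 0.8 by
default). Yield = v_obj / v_c with v_c the CO2 uptake (bicarbonate uptake is
summed in and logged when present). Missing secretion routes are added
automatically and recorded; heterologous pathways are supplied as reaction
lists, are validated for elemental balance where formulas exist, extend a
copy of the model, and are tagged `gap_filled`.

## The synthetic photoautotroph

The toy generator emulates the network motifs of a cyanobacterial GSMM at
12–40 reactions: Z-scheme linear electron flow (8 photons → 1 O2 + 2 NADPH
+ proton motive force for 3 ATP), cyclic electron flow (2 photons → 1 ATP),
ATP synthase, a lumped Calvin-cycle reaction (3 CO2 + 6 NADPH + 9 ATP →
triose phosphate), an optional glycogen branch, lower glycolysis, lumped
acetyl and 2-oxoglutarate formation, the 2-OG → succinic semialdehyde →
succinate shunt (secretion-only, orphan-tagged), nitrate reduction with
GS-GOGAT (or a one-step GDH variant), lumped C16 fatty-acid synthesis, and a
biomass equation composed from a three-component composition (glutamyl
0.41 / glucosyl 0.52 / palmitoyl 0.037 mass fractions — magnitudes chosen to
match a glycogen-rich marine cyanobacterium). Photons and the proton-motive
pseudo-metabolite are massless; every other reaction is elementally
balanced, which the test suite asserts.

Because the network is tree-shaped (no redundant routes), all internal
fluxes are forced by the biomass demands; linear electron flow is set by the
NADPH balance, cyclic flow closes the ATP balance, and the photon cap yields
the closed-form maximal growth μ = (P − 2·NGAM)/(D_NADPH + 2·D_ATP). The
generator ships this flux map, the maximal growth and the essential set
(route support minus the maintenance drain) as ground truth, and the test
suite checks the LP solver, the pFBA map, and the essentiality screen
against them — plus against brute-force vertex enumeration and an
independent GLPK backend on small instances.

What the toy does *not* emulate: alternative pathways and redundancy (so
essentiality on the toy is maximal by construction), NADH/NADPH distinction,
proton and charge balancing, photorespiration, and realistic subsystem
sizes. Passing the toy-based tests therefore validates the algorithms and
bookkeeping, not the biology of any genome-scale reconstruction.

Gap injection removes named (or seeded-random) internal reactions, never
exchanges/biomass/sink/maintenance; loop injection adds a two-reaction
cycle that emits proton-motive quanta from nothing — mass-balanced but
thermodynamically impossible, exactly the signature the loop detector and
ATP-from-nothing test must catch.

## Numerical and design choices

- Default bounds where SBML files omit them: ±1000 (reversible) or 0/1000
  (irreversible), with a logged warning.
- Exchange detection: category tag when present, single-metabolite
  heuristic otherwise.
- Photoautotrophic medium: inorganic carbon, photon, nitrate/ammonium,
  phosphate, sulfate, water, protons, O2 and common ions stay open (a
  tighter model-side uptake bound such as a photon cap is preserved);
  all other exchanges have uptake closed, secretion untouched.
- SBML ids are sanitized reversibly (`__uXXXX__` escapes); subsystem,
  category and evidence tags travel in reaction notes.
- Problem sizes: the shipped tests run entirely on the toy models (34
  reactions), where a full essentiality screen is a few dozen LPs; the
  genome-scale tier of the acceptance tests activates only when a published
  reconstruction file is provided.

## Known limitations

- Biomass coefficients carry no uncertainty propagation from measurement
  SDs.
- The amino-acid, nucleotide and lipid templates are literature defaults,
  not strain measurements; the derived formula and γ inherit that
  approximation (~1% on γ for realistic compositions).
- pFBA flux maps are reported from one optimum; degeneracy is only
  quantified on request via flux variability.
- No gene-level deletions (reaction-level only), no automated gap filling,
  no elementary-flux-mode analysis, no strain-design algorithms.
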