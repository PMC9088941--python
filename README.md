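# quenchbind

Characterising how a small molecule binds a protein from fluorescence
titrations — quenching mechanism, binding constants, thermodynamic driving
force — together with the structural probes (time-resolved fluorescence,
synchronous scans, 3D excitation–emission matrices, CD), enzyme-activity
arithmetic and post-MD trajectory observables that round out such a study.
The reference system used throughout the tests and examples is the gastric
protease **pepsin** titrated with the oral iron chelator **deferasirox
(DFX)**.

Intended users: spectroscopists and computational chemists who have
instrument exports (CSV spectra, TCSPC histograms, OD tables) or multi-model
PDB trajectories and want the standard binding-characterisation numbers with
a transparent, testable provenance. Because raw instrument data is rarely
deposited, every input class can also be *simulated* with known ground
truth, so the whole chain is verifiable by round trip.

## The models

**Stern–Volmer quenching.** With F₀ (F) the emission intensity without
(with) quencher at concentration [Q]:

    F₀/F = 1 + K_SV [Q]

The bimolecular quenching rate constant K_q = K_SV/τ₀ (τ₀ the unquenched
fluorescence lifetime) separates mechanisms: diffusion caps collisional
(dynamic) quenching at K_q ≈ 2×10¹⁰ L mol⁻¹ s⁻¹; values far above it, a
K_SV that *falls* with temperature, and an unchanged lifetime all indicate
ground-state complex formation (static quenching). `classify_mechanism`
votes over these three criteria and labels the system only when at least
two agree and none contradicts.

**Binding constant and site number.** For a static quencher,

    lg[(F₀ − F)/F] = lg K_a + n lg[Q]

gives K_a = 10^intercept and the apparent number of high-affinity sites n.

**Thermodynamics.** Van't Hoff regression of ln K_a on 1/T yields
ΔH = −R·slope and ΔS = R·intercept; ΔG = ΔH − TΔS. The (ΔH, ΔS) signs
classify the dominant force (Ross rules): both negative → hydrogen
bonding/van der Waals; both positive → hydrophobic; ΔH<0, ΔS>0 →
electrostatic.

**Lifetimes.** TCSPC decays are tail-fitted with 1–3 exponentials under
Poisson weights; the amplitude-weighted mean lifetime is
τ_ave = Σ αᵢτᵢ.

**Trajectories.** Kabsch-superposed RMSD, per-residue RMSF, radius of
gyration, closest-atom ligand–residue distances, and geometric
hydrogen-bond counts (H⋯A ≤ 3.5 Å, D–H⋯A ≥ 120° by default) on
multi-model PDB input.

## Worked example

Simulate three titrations at the study's ladder (0–24 µM quencher, 16 µM
protein) from the per-temperature binding laws, then run the full chain:

```python
from quenchbind import *
from quenchbind.lifetime import LifetimeFit

truth = [(298.0, 4.142e4, 8.978e4, 1.073),
         (304.0, 3.447e4, 4.998e4, 1.039),
         (310.0, 2.338e4, 1.782e4, 0.972)]
tau0 = mean_lifetime(LifetimeFit.from_components(
    (1.836, 5.719, 0.474), (16.71, 76.01, 7.27), percent=True))  # 4.688 ns

sv_fits, bind_fits = [], []
for T, ksv, ka, n in truth:
    s = simulate_titration(QuenchSimSpec(ksv_true=ksv, ka_true=ka, n_true=n),
                           T, law="double_log")
    r = quench_ratios(s)
    sv_fits.append(stern_volmer_fit(r, T, tau0_ns=tau0))
    bind_fits.append(double_log_fit(r, T))

print(classify_mechanism(sv_fits, lifetime_invariant=True).label)
res = vant_hoff({b.temperature: b.ka for b in bind_fits})
print(f"dH={res.delta_h:.2f} kJ/mol  dS={res.delta_s:.2f} J/mol/K "
      f"force={res.force_label}")
```

Output:

```
static
dH=-103.30 kJ/mol  dS=-251.16 J/mol/K force=hydrogen-bond/van-der-Waals
```

The K_q at 298 K is 8.86×10¹² L mol⁻¹ s⁻¹ — almost three orders of
magnitude above the diffusion ceiling — and all three ΔG values are
negative (−28.45, −26.94, −25.44 kJ/mol at 298/304/310 K), so binding is
spontaneous, static, and enthalpy-driven: hydrogen bonding and van der
Waals contacts dominate. The binding fits recover K_a and n ≈ 1 exactly on
noiseless input, consistent with a single high-affinity site.

The same chain is scriptable from the shell:

```sh
quenchbind simulate titration --ksv 41420 --seed 3 titr.csv
quenchbind quench --tau0-ns 4.688 titr.csv
quenchbind run study.yaml        # whole pipeline from a YAML config
```

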