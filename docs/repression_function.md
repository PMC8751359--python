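# Derivation of the closed-form repression functions

All repression functions in `circlock.models` are instances of one
quadratic free-activator formula.  This note derives the effective-constant
mapping implemented by `models.effective_constants` from the explicit
mass-action binding schemes.  The mapping is validated in the test suite
against numerically solved equilibria of the explicit subnetworks
(`tests/test_models.py`, < 1e-6 relative error on randomized draws).

## 1. Pure titration

A sequestrant at total concentration `R_T` binds an activator pool `A_T`
with dissociation constant `Kd` (`A·Rf = Kd·C`, `C` the complex).  With
`A_T = A + C` and `R_T = Rf + C`,

    A^2 + (R_T - A_T + Kd) A - Kd A_T = 0
    A = (A_T - R_T - Kd + sqrt((A_T - R_T - Kd)^2 + 4 Kd A_T)) / 2

This is `free_kaiA`; dividing by `A_T` gives the free-activator fraction
(`kim_forger_f`).  The two are the same quadratic, which the test suite
asserts to machine precision.

## 2. Locked repressor chain (no activator phosphorylation)

Scheme (the phosphorylated complex cannot dissociate through the binding
step; it only resolves through `k3`, which removes the phosphorylated
repressor and frees the activator):

    A + R  <-> AR     (k1f, k1r)
    AR     <-> ARp    (k2f, k2r)
    ARp    ->  A + (repressor removed)   (k3)

Quasi-steady state of the two complexes with the total repressor pool held
by the slow chain dynamics:

    ARp = phi * AR,              phi = k2f / (k2r + k3)
    k1f * A * Rf = AR * (k1r + k2f*k3/(k2r + k3)) = AR * D

Both complexes count toward both conservation laws
(`A_T = A + (1+phi) AR`, `R_T = Rf + (1+phi) AR`), so the system is pure
titration with

    Kd_eff = D / ((1 + phi) k1f)
           = (k1r (k2r + k3) + k2f k3) / (k1f (k2f + k2r + k3))

In the homogeneous form used by the quadratic: `K1 = k1f (k2f + k2r + k3)`,
`K2 = k1r (k2r + k3) + k2f k3`, `K3 = K1`.

Limiting cases:

* `k2f = 0, k3 = 0`: `Kd_eff = k1r/k1f` — plain sequestration.
* `k2f >> k2r` (strong lock phosphorylation) with small `k3`:
  `Kd_eff -> k3 (k1r + k2f) / (k1f (k2f + k3)) ~ k3/k1f` — the lock makes
  binding effectively tighter than `k1r/k1f` whenever `k3 < k1r`, which is
  why strong phosphorylation rescues oscillations at weak binding
  affinities.
* `k2r >> k2f` (strong dephosphorylation): `Kd_eff -> k1r/k1f` — the lock
  is never engaged and the bare affinity rules, so at tight binding the
  dephosphorylation-dominated regime oscillates most readily.

## 3. Added activator phosphorylation

Two changes: free activator interconverts with an inactive phosphoform,
and resolution of the locked complex releases the activator in its
*phosphorylated* (inactive) form while recycling the repressor:

    A   <-> Ap        (k4f, k4r),  k4 = k4f/k4r
    ARp ->  Ap + R    (k3)

Quasi-steady state now gives an extra inactive-activator pool fed by the
lock (`Ap = k4 A + (k3 phi / k4r) AR`), so the conservation laws weight the
complex differently on the two sides:

    A_T = A (1 + k4) + w_A * AR,   w_A = 1 + phi + k3 phi / k4r
    R_T = Rf + w_R * AR,           w_R = 1 + phi

Solving the resulting quadratic for `A` and matching coefficients yields
(common scale `k1f (k2r + k3)` applied so the first two constants coincide
with section 2):

    K1 = k1f (k2f + k2r + k3)
    K2 = k1r (k2r + k3) + k2f k3
    K3 = K1 + k1f k3 k2f / k4r

with the free activator

    f(R) = (K1 A_T - K3 R - K2 (1+k4)
            + sqrt((K1 A_T + K3 R + K2 (1+k4))^2 - 4 K1 K3 A_T R))
           / (2 K1 (1+k4))

`K3 > K1` is the mathematical footprint of catalytic inactivation: each
repressor passing through the lock parks one activator in the
phosphorylated pool, so a sub-stoichiometric amount of repressor can
neutralize the activator pool.  This is what widens the distribution of
steady-state repressor:activator ratios as `k3` grows, and lets the ratio
approach zero (`K1/K3 -> 0` as `k3 k2f / k4r` grows).

Identities (asserted in tests): `f(0) = A_T / (1 + k4)`; setting `k4 = 0`
and `K3 = K1` recovers section 2's function exactly.

## 4. Steady-state repressor equation

For the chain `dM = a1 f(R) - b1 M`, `dr = a2 M - b2 r`,
`dR = a3 r - b3 R`, the fixed point satisfies

    f(R*) = (b1 b2 b3 / (a1 a2 a3)) R*

The left side can equivalently be written through the bound-complex
radical `(A_T - K3*AR(R))/(1+k4)` (the minus-root of the same quadratic);
`analysis.steady_state_repressor` uses this form and brackets the root in
`[0, A_T a1 a2 a3/(b1 b2 b3) + 1]`, where a sign change is guaranteed
because the left side is bounded by `A_T` and the right side is linear.
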