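"""Mechanical metrics from tensile and AFM-indentation curves.

Generates a noisy Hertzian approach curve (E = 1 GPa, ν = 0.3,
R = 10 nm, k_c = 200 N/m) and a linear-elastic stress–strain curve,
then recovers the moduli, fracture metrics and point stiffness.
"""

from helixrope import (gen_indent_curve, gen_tensile_curve, hertz_fit,
                       point_stiffness, tensile_metrics)

curve, truth = gen_indent_curve(E=1e9, nu=0.3, tip_radius=10e-9,
                                spring_constant=200.0, noise_frac=0.01, seed=3)
fit = hertz_fit(curve)
print(f"Hertz fit: E = {fit.modulus / 1e9:.3f} GPa "
      f"(truth {truth['E'] / 1e9:.1f} GPa), "
      f"contact point {fit.contact_point * 1e9:+.2f} nm")
k = point_stiffness(curve, contact_point=fit.contact_point)
print(f"point stiffness at maximum load: {k:.1f} N/m "
      "(force over deflection-corrected sample deformation)")

tcurve, ttruth = gen_tensile_curve(0.85e9, fracture_strain=0.012,
                                   noise_frac=0.005, seed=4)
m = tensile_metrics(tcurve)    # modulus from the 0-0.2 % strain window
print(f"tensile modulus {m.modulus / 1e9:.2f} GPa "
      f"(truth {ttruth['modulus'] / 1e9:.2f}), "
      f"fracture stress {m.fracture_stress / 1e6:.1f} MPa, "
      f"work of rupture {m.work_of_rupture / 1e6:.3f} MJ/m³")
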