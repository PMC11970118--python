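"""Physical constants and package-wide defaults (atomic units internally)."""

#: Conversion factor from angstrom to bohr.
BOHR_PER_ANGSTROM = 1.8897259886

#: Default isotropic polarizability of a Na+ site, bohr^3.  Sodium's electron
#: density is very contracted, so its contribution to molecular polarizability
#: is close to negligible.
NA_POLARIZABILITY = 0.3

#: Default isotropic polarizability of a Cl- site, bohr^3.  A bound chloride
#: adds on the order of 30 bohr^3 to the molecular polarizability.
CL_POLARIZABILITY = 30.0

#: Default isotropic polarizability of a water molecule (single site at the
#: oxygen position), bohr^3.  Standard gas-phase literature value.
WATER_POLARIZABILITY = 9.8

#: Default Thole damping coefficient b (dimensionless), the value commonly
#: used in Drude polarizable force fields.
DEFAULT_THOLE_B = 2.6

#: Distance threshold for Cl- binding to a basic group, via the shortest
#: H...Cl contact (angstrom).
CL_BIND_THRESHOLD = 2.5

#: Distance threshold for Na+ binding to a carboxylate group, via the
#: shortest O...Na contact (angstrom).
NA_BIND_THRESHOLD = 3.5

#: Default ellipsoid-inflation cutoff used when trimming the water shell
#: around the protein (angstrom).
DEFAULT_CUTOFF = 8.0
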