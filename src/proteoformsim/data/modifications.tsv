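# Post-translational modifications modelled at the chemistry level.
# adds_groups: semicolon list of ionizable groups gained per modified site.
# removes_site_group: "yes" if the modification silences the ionizable side chain of
# the residue it sits on (phospho-Tyr loses the phenol; acetyl-Lys loses the amine).
# allowed_residues: residues the modification may be placed on ("nterm" = chain start).
name	mass_delta_average_da	mass_delta_monoisotopic_da	adds_groups	removes_site_group	allowed_residues
phospho	79.9799	79.96633	phospho_1;phospho_2	yes	STY
acetyl	42.0367	42.01057	-	yes	K,nterm
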