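fs_name,structure,hemisphere
Left-Amygdala,Amygdala,left
Right-Amygdala,Amygdala,right
Left-Accumbens-area,Accumbens-area,left
Right-Accumbens-area,Accumbens-area,right
Left-Pallidum,Pallidum,left
Right-Pallidum,Pallidum,right
Left-Caudate,Caudate,left
Right-Caudate,Caudate,right
Left-Hippocampus,Hippocampus,left
Right-Hippocampus,Hippocampus,right
Left-Putamen,Putamen,left
Right-Putamen,Putamen,right
Left-Thalamus-Proper,Thalamus,left
Right-Thalamus-Proper,Thalamus,right
Left-Thalamus,Thalamus,left
Right-Thalamus,Thalamus,right
Left-VentralDC,VentralDC,left
Right-VentralDC,VentralDC,right
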