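# Genes differentially expressed 1 day after status epilepticus in all 5 SE laboratories and all 3 SE models (GSE47752 consortium reference list)
Aard
Abcd2
Acvr1c
Arsg
Boc
C1s
Ca10
Car11
Cbfb
Clmp
Col25a1
Crim1
Cyb561
Dclk3
Ddit4l///LOC100363484
Ddr2
Enox2
Extl1
Fam129b
Fam69c
Fat1
Gabrd
Gadl1
Gdf10
Gpc3
Htr5b
Ifitm10
Khdrbs3
Kifc3
Klf15
Klhl5
Lingo2
LOC100910632
LOC100910797
LOC100911253
LOC100912459
LOC102552294
LOC102548876
LOC102551251
LOC691995
Lox
Lrig1
Mmp9
Mpp6
Nhlh1
Nmb
Npdc1
Ntf3
Nubpl
Plk5
Podxl2
Prkacb
Prss23
Ptpn5
Ptprn
Rab26
Rbks
Rbp1
Rnasel
Rreb1
Rsph10b
Scn4b
Serinc2
Shb
Sim2
Ss18
Ssbp3
Tbc1d2b
Trh
Tut1
Wls
Zfp259
Zmiz1
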