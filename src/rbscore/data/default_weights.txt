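# default weights -- fitted by this package's simulated-annealing trainer on 12 synthetic fixture complexes (synthetic data, NON-canonical); training wAUC 0.9954 at the 3.5 A cutoff. Supply your own weight file for real structures.
w_aa.ALA=0.03299955535207843
w_aa.ARG=0.03299955535207843
w_aa.ASN=0.03299955535207843
w_aa.ASP=0.04779927491653488
w_aa.CYS=0.03299955535207843
w_aa.GLN=0.03299955535207843
w_aa.GLU=0.03250529549315029
w_aa.GLY=0.03299955535207843
w_aa.HIS=0.03299955535207843
w_aa.ILE=0.029868795872860385
w_aa.LEU=0.03299955535207843
w_aa.LYS=0.03299955535207843
w_aa.MET=0.03299955535207843
w_aa.PHE=0.024837301297892835
w_aa.PRO=0.03586179883220736
w_aa.SER=0.03299955535207843
w_aa.THR=0.03299955535207843
w_aa.TRP=0.026258443694651405
w_aa.TYR=0.03299955535207843
w_aa.VAL=0.03299955535207843
w_elec.0=-2.031701331913711e-06
w_elec.1=-0.000352097705110961
w_elec.2=-0.0005534584497100077
w_elec.3=0.00022473104793460235
w_elec.4=-0.0004403564359906459
w_elec.5=0.000999589248185997
w_elec.6=0.0029116585485662707
w_elec.7=0.0011177252297765003
w_elec.8=0.002464423370990887
w_elec.9=0.0013052286208114167
w_CE=0.23510603745750355
w_width=0.31847133075958023
C_aa.ALA=0.0
C_aa.ARG=0.0
C_aa.ASN=0.0
C_aa.ASP=0.0
C_aa.CYS=0.0
C_aa.GLN=0.0219266438618447
C_aa.GLU=0.0677383375632535
C_aa.GLY=0.0
C_aa.HIS=0.0
C_aa.ILE=0.028050560535122736
C_aa.LEU=0.0
C_aa.LYS=0.0
C_aa.MET=0.0
C_aa.PHE=-0.032929433888877965
C_aa.PRO=-0.02173782747611347
C_aa.SER=0.0
C_aa.THR=-0.025645431921992378
C_aa.TRP=-0.01918027298143808
C_aa.TYR=0.0
C_aa.VAL=0.0
u_aa.ALA=0.5
u_aa.ARG=0.5
u_aa.ASN=0.5
u_aa.ASP=0.5
u_aa.CYS=0.5
u_aa.GLN=0.5
u_aa.GLU=0.5
u_aa.GLY=0.5
u_aa.HIS=0.5
u_aa.ILE=0.5
u_aa.LEU=0.5
u_aa.LYS=0.5
u_aa.MET=0.5
u_aa.PHE=0.5
u_aa.PRO=0.6018370344607842
u_aa.SER=0.5
u_aa.THR=0.5
u_aa.TRP=0.5
u_aa.TYR=0.5
u_aa.VAL=0.5
v_aa.ALA=0.5
v_aa.ARG=0.4294441018560807
v_aa.ASN=0.5
v_aa.ASP=0.5
v_aa.CYS=0.5
v_aa.GLN=0.4231635906392694
v_aa.GLU=0.6833812008011045
v_aa.GLY=0.5
v_aa.HIS=0.6410847074586821
v_aa.ILE=0.5
v_aa.LEU=0.5
v_aa.LYS=0.532803289509352
v_aa.MET=0.5
v_aa.PHE=0.3711061305675143
v_aa.PRO=0.5
v_aa.SER=0.5
v_aa.THR=0.5
v_aa.TRP=0.5
v_aa.TYR=0.5
v_aa.VAL=0.5
f.PEPTIDE_HIGH=1.157895025245713
f.PEPTIDE_LOW=1.0
f.LOCAL_HIGH=1.1847938267726488
f.LOCAL_LOW=0.8780754950846154
f.SPATIAL_HIGH=1.0
f.SPATIAL_LOW=1.1629462804915585
g.PEPTIDE_HIGH=1.0
g.PEPTIDE_LOW=1.0
g.LOCAL_HIGH=1.0
g.LOCAL_LOW=1.0
g.SPATIAL_HIGH=1.0
g.SPATIAL_LOW=1.0
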