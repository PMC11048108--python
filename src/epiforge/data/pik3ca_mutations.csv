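mutation,cancer_type
R38H,Colorectal Adenocarcinoma
R88Q,Colorectal Adenocarcinoma
G106V,Colorectal Adenocarcinoma
C420R,Colorectal Adenocarcinoma
E453Q,Colorectal Adenocarcinoma
E542K,Colorectal Adenocarcinoma
E545K,Colorectal Adenocarcinoma
R1023Q,Colorectal Adenocarcinoma
M1043I,Colorectal Adenocarcinoma
H1047R,Colorectal Adenocarcinoma
R108H,Meningioma
E110K,Meningioma
Y165H,Meningioma
N345K,Meningioma
I391M,Meningioma
E453K,Meningioma
E545K,Meningioma
G914R,Meningioma
H1047R,Meningioma
E81K,Breast Cancer
K111E,Breast Cancer
G118D,Breast Cancer
N345K,Breast Cancer
S405P,Breast Cancer
C420R,Breast Cancer
E453K,Breast Cancer
E542K,Breast Cancer
E542V,Breast Cancer
E545A,Breast Cancer
E545G,Breast Cancer
E545K,Breast Cancer
Q546E,Breast Cancer
Q546K,Breast Cancer
Q546R,Breast Cancer
E726K,Breast Cancer
H1047L,Breast Cancer
H1047R,Breast Cancer
M1043I,Breast Cancer
N1044K,Breast Cancer
G1049R,Breast Cancer
E542K,Endometrial Cancer
E542Q,Endometrial Cancer
E545K,Endometrial Cancer
E545G,Endometrial Cancer
G1007R,Endometrial Cancer
Y1021H,Endometrial Cancer
Y1021C,Endometrial Cancer
A1035V,Endometrial Cancer
M1043I,Endometrial Cancer
H1047Y,Endometrial Cancer
H1047R,Endometrial Cancer
G1050D,Endometrial Cancer
T1052K,Endometrial Cancer
H1065L,Endometrial Cancer
R88E,Glioblastoma Multiforme
R88Q,Glioblastoma Multiforme
P298T,Glioblastoma Multiforme
R310C,Glioblastoma Multiforme
V344G,Glioblastoma Multiforme
E453K,Glioblastoma Multiforme
E542K,Glioblastoma Multiforme
E545A,Glioblastoma Multiforme
E545K,Glioblastoma Multiforme
Y1021C,Glioblastoma Multiforme
Y1021N,Glioblastoma Multiforme
T1025N,Glioblastoma Multiforme
T1031G,Glioblastoma Multiforme
M1043I,Glioblastoma Multiforme
N1044S,Glioblastoma Multiforme
H1047Y,Glioblastoma Multiforme
G1049S,Glioblastoma Multiforme
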